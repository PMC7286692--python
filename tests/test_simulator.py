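"""Face-cell drive model and Poisson session simulation."""

import numpy as np
import pytest

from facecontext import scenes, simulator
from facecontext.geometry import Ellipse
from facecontext.region_stats import halfmax_latency
from facecontext.simulator import (FaceCellModel, alpha_kernel, drive_rate,
                                   make_array, simulate_probe_session,
                                   simulate_session)


def _kernel_peak_ms(rise, decay):
    return rise * decay / (decay - rise) * np.log(decay / rise)


def _cell(**kw):
    defaults = dict(rf_center_deg=(0.0, 0.0), rf_sigma_deg=1.0,
                    baseline_hz=5.0)
    defaults.update(kw)
    return FaceCellModel(**defaults)


def _face_scene(pos=(0.0, 0.0), scene_id="s"):
    return scenes.SceneSpec(scene_id,
                            [scenes.Region("face", Ellipse(pos, 0.8, 1.0))],
                            "intact")


def test_kernel_unit_peak_and_causality():
    t = np.linspace(-50, 600, 5000)
    k = alpha_kernel(t, 10.0, 150.0)
    assert np.all(k[t < 0] == 0)
    assert abs(k.max() - 1.0) < 1e-3
    tp = _kernel_peak_ms(10.0, 150.0)
    assert abs(alpha_kernel(tp, 10.0, 150.0) - 1.0) < 1e-12


def test_face_on_rf_peak_rate_is_baseline_plus_gain():
    cell = _cell()
    scene = _face_scene()
    tp = cell.latencies_ms["face"] + _kernel_peak_ms(cell.rise_ms, cell.decay_ms)
    rate = drive_rate(cell, scene, (0.0, 0.0), np.array([tp]))[0]
    assert abs(rate - (cell.baseline_hz + cell.gains["face"])) < 1e-9


def test_distant_implied_face_leaves_baseline():
    (scene,) = scenes.make_scene_set("occluded", 1, seed=0)
    body = scene.regions_by("body")[0]
    cell = _cell(rf_center_deg=(body.implied_face[0] + 10.0,
                                body.implied_face[1]))
    t = np.arange(0, 350, 1.0)
    # present so the anchor stays 10 deg from the RF
    rate = drive_rate(cell, scene, (0.0, 0.0), t)
    assert np.allclose(rate, cell.baseline_hz, atol=1e-6)


def test_occluded_face_response_begins_after_context_latency():
    (scene,) = scenes.make_scene_set("occluded", 1, seed=0)
    body = scene.regions_by("body")[0]
    cell = _cell()
    # grid position that centres the implied face on the RF
    g = (cell.rf_center_deg[0] - body.implied_face[0],
         cell.rf_center_deg[1] - body.implied_face[1])
    lat = cell.latencies_ms["context_implied_face"]
    t = np.arange(0, 350, 1.0)
    rate = drive_rate(cell, scene, g, t)
    assert np.allclose(rate[t <= lat], cell.baseline_hz, atol=1e-6)
    assert rate[int(lat) + 20] > cell.baseline_hz + 1.0


def test_rate_never_negative():
    cell = _cell(inversion_attenuation=0.0)
    t = np.arange(0, 400, 1.0)
    for arch in ("intact", "occluded", "upright_inverted"):
        for scene in scenes.make_scene_set(arch, 1, seed=2):
            for g in [(-2, 1), (0, 0), (3, -3)]:
                assert np.all(drive_rate(cell, scene, g, t) >= 0)


def test_ceiling_rule_body_below_intact_face_changes_nothing():
    face = scenes.Region("face", Ellipse((0.0, 2.0), 0.8, 1.0))
    alone = scenes.SceneSpec("alone", [face], "intact")
    with_body = scenes.SceneSpec(
        "with_body", [face, scenes._body_region((0.0, 2.0))], "intact")
    cell = _cell(gains={"eyes": 0.0, "face": 40.0,
                        "context_implied_face": 16.0, "context_feet": 0.0})
    t = np.arange(0, 350, 1.0)
    for g in [(0.0, -2.0), (1.0, 0.0)]:
        assert np.array_equal(drive_rate(cell, alone, g, t),
                              drive_rate(cell, with_body, g, t))


def test_ceiling_rule_off_restores_context_drive():
    face = scenes.Region("face", Ellipse((0.0, 0.0), 0.8, 1.0))
    with_body = scenes.SceneSpec(
        "wb", [face, scenes._body_region((0.0, 0.0))], "intact")
    on = _cell(ceiling_rule=True)
    off = _cell(ceiling_rule=False)
    t = np.array([200.0])
    assert drive_rate(off, with_body, (0, 0), t)[0] > \
        drive_rate(on, with_body, (0, 0), t)[0]


def test_halfmax_latency_matches_configured_latency():
    cell = _cell()
    t = np.arange(0, 350, 1.0)
    rate = drive_rate(cell, _face_scene(), (0.0, 0.0), t)
    lat = halfmax_latency(rate, baseline_ms=(0, 80))
    assert abs(lat - cell.latencies_ms["face"]) <= cell.rise_ms


def test_pl_precedes_ml():
    t = np.arange(0, 350, 1.0)
    scene = _face_scene()
    lat = {}
    for area, off in [("PL", -10.0), ("ML", 0.0)]:
        cell = _cell(latency_offset_ms=off)
        lat[area] = halfmax_latency(drive_rate(cell, scene, (0, 0), t),
                                    baseline_ms=(0, 70))
    assert lat["PL"] < lat["ML"]


def test_inversion_sustained_for_noise_transient_for_faces():
    pairs = {}
    for s in scenes.make_scene_set("upright_inverted", 1, seed=0):
        pairs.setdefault((s.meta["variant"], s.meta["inverted"]), s)
    cell = _cell()
    pf = pairs[("face", False)].regions_by("face_region", by="name")[0].center
    g = (cell.rf_center_deg[0] - pf[0], cell.rf_center_deg[1] - pf[1])
    t_sus = np.array([220.0])
    t_rise = np.array([cell.latencies_ms["face"] + 5.0])
    # ambiguous noise: sustained attenuation when inverted
    up = drive_rate(cell, pairs[("noise_patch", False)], g, t_sus)[0]
    inv = drive_rate(cell, pairs[("noise_patch", True)], g, t_sus)[0]
    assert inv < up
    # intact face: difference confined to the kernel rise
    up_f = drive_rate(cell, pairs[("face", False)], g, t_sus)[0]
    inv_f = drive_rate(cell, pairs[("face", True)], g, t_sus)[0]
    # only the (attenuated) far-away feet-context drive differs: < 1e-3 Hz
    assert abs(up_f - inv_f) < 1e-3
    assert drive_rate(cell, pairs[("face", True)], g, t_rise)[0] < \
        drive_rate(cell, pairs[("face", False)], g, t_rise)[0]


def test_session_baseline_poisson_count():
    cell = _cell(baseline_hz=10.0,
                 gains={k: 0.0 for k in simulator.DRIVE_KINDS})
    array = simulator.ArrayModel([cell])
    scene = _face_scene()
    protocol = scenes.make_protocol(3, 2.0, (0, 0), [scene], reps=30, seed=0)
    record = simulate_session(array, protocol, [scene], seed=1)
    expected = 10.0 * record.duration_ms / 1000.0
    count = record.spike_times[0].size
    assert abs(count - expected) < 4 * np.sqrt(expected)


def test_session_seed_reproducible():
    array = make_array(2, seed=0)
    scene_set = scenes.make_scene_set("intact", 1, seed=0)
    protocol = scenes.make_protocol(3, 2.0, array.rf_center, scene_set, 5, 1)
    r1 = simulate_session(array, protocol, scene_set, seed=42)
    r2 = simulate_session(array, protocol, scene_set, seed=42)
    r3 = simulate_session(array, protocol, scene_set, seed=43)
    for ch in r1.channels:
        assert np.array_equal(r1.spike_times[ch], r2.spike_times[ch])
    assert not np.array_equal(r1.spike_times[0], r3.spike_times[0])


def test_evoked_count_scales_linearly_with_gain():
    scene = _face_scene()
    counts = {}
    for gain in (20.0, 40.0):
        cell = _cell(baseline_hz=2.0,
                     gains={"eyes": 0.0, "face": gain,
                            "context_implied_face": 0.0, "context_feet": 0.0})
        array = simulator.ArrayModel([cell])
        protocol = scenes.make_protocol(1, 2.0, (0.0, 0.0), [scene],
                                        reps=200, seed=3)
        record = simulate_session(array, protocol, [scene], seed=4)
        onsets = protocol.events["onset_ms"].to_numpy(float)
        total = record.counts_in_window(0, onsets, (95.0, 345.0)).mean()
        counts[gain] = total - 2.0 * 0.25   # subtract expected baseline count
    ratio = counts[40.0] / counts[20.0]
    assert abs(ratio - 2.0) < 0.15


def test_probe_session_grid_and_unknown_scene_error():
    array = make_array(1, seed=0)
    record, protocol, probe_scenes = simulate_probe_session(
        array, grid_shape=5, spacing_deg=1.0, reps=5, seed=0)
    assert len(protocol.events) == 25 * 5
    with pytest.raises(KeyError):
        simulate_session(array, protocol, [], seed=0)


def test_spike_record_round_trip_csv(tmp_path):
    array = make_array(2, seed=1)
    scene_set = scenes.make_scene_set("intact", 1, seed=0)
    protocol = scenes.make_protocol(3, 2.0, array.rf_center, scene_set, 5, 1)
    record = simulate_session(array, protocol, scene_set, seed=5)
    path = tmp_path / "spikes.csv"
    record.to_csv(path)
    import pandas as pd
    loaded = simulator.SpikeRecord.from_frame(pd.read_csv(path))
    for ch in record.channels:
        assert np.allclose(loaded.spike_times[ch], record.spike_times[ch])
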