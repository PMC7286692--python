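"""Response-map registration, interpolation, scaling, composites."""

import numpy as np
import pytest

from facecontext import response_maps, scenes, simulator
from facecontext.geometry import Ellipse
from facecontext.response_maps import (ResponseMap, build_scene_response_map,
                                       composite_orientation_map,
                                       image_coordinate, interpolate_map,
                                       oracle_scene_response_map,
                                       population_map, scale_map,
                                       temporal_maps)

RF = (1.0, -0.5)


def _delta_setup(c_star, rf_sigma=0.5, gain=80.0):
    cell = simulator.FaceCellModel(
        rf_center_deg=RF, rf_sigma_deg=rf_sigma, baseline_hz=2.0,
        gains={"eyes": 0.0, "face": gain, "context_implied_face": 0.0,
               "context_feet": 0.0})
    array = simulator.ArrayModel([cell])
    scene = scenes.SceneSpec(
        "delta", [scenes.Region("face", Ellipse(c_star, 0.8, 1.0))], "intact")
    protocol = scenes.make_protocol(9, 2.0, RF, [scene], reps=20, seed=0)
    return cell, array, scene, protocol


@pytest.mark.parametrize("c_star", [(2.0, 2.0), (-4.0, 4.0), (4.0, -2.0)])
def test_registration_argmax_no_mirror(c_star):
    """A responder driven only by image coordinate c* must reconstruct with
    its argmax at c*, not at -c* (sign/mirror errors)."""
    cell, array, scene, protocol = _delta_setup(c_star)
    record = simulator.simulate_session(array, protocol, [scene], seed=1)
    m = build_scene_response_map(record, protocol, "delta", 0, RF)
    assert m.argmax_coord() == c_star
    oracle = oracle_scene_response_map(cell, protocol, scene, RF)
    assert oracle.argmax_coord() == c_star
    r = np.corrcoef(m.values.ravel(), oracle.values.ravel())[0, 1]
    assert r > 0.95


def test_image_coordinate_convention():
    cx, cy = image_coordinate(RF, 3.0, -2.5)
    assert (cx, cy) == (-2.0, 2.0)


def test_position_independent_responder_flat_map():
    cell = simulator.FaceCellModel(
        baseline_hz=20.0, gains={k: 0.0 for k in simulator.DRIVE_KINDS})
    array = simulator.ArrayModel([cell])
    scene = scenes.SceneSpec(
        "flat", [scenes.Region("face", Ellipse((0.0, 0.0), 0.8, 1.0))],
        "intact")
    protocol = scenes.make_protocol(5, 2.0, RF, [scene], reps=10, seed=2)
    record = simulator.simulate_session(array, protocol, [scene], seed=3)
    m = build_scene_response_map(record, protocol, "flat", 0, RF)
    assert m.values.std() < 5.5   # sampling error of 20 Hz over 150 ms x 10


def test_intact_scene_map_peaks_in_face_region(small_session):
    s = small_session
    scene = s["intact"][0]
    m = build_scene_response_map(s["record"], s["protocol"], scene.scene_id,
                                 "population", s["array"].rf_center)
    cx, cy = m.argmax_coord()
    face = scene.regions_by("face")[0]
    assert face.shape.contains(cx, cy)


def test_map_absent_scene_rejected(small_session):
    s = small_session
    with pytest.raises(KeyError):
        build_scene_response_map(s["record"], s["protocol"], "nope", 0, RF)


def test_interpolation_preserves_nodes_and_bilinearity(rng):
    values = rng.normal(size=(5, 7))
    m = ResponseMap("m", 0, np.arange(7.0), np.arange(5.0), values)
    dense = interpolate_map(m, px_per_deg=2)
    # nodes appear exactly at even dense indices
    assert np.allclose(dense.values[::2, ::2], values, atol=1e-12)
    # midpoint of 4 nodes equals their mean
    mid = dense.values[1, 1]
    assert abs(mid - values[:2, :2].mean()) < 1e-12
    assert dense.values.max() <= values.max() + 1e-12
    assert dense.values.min() >= values.min() - 1e-12


def test_interpolation_matches_two_pass_oracle(rng):
    values = rng.normal(size=(4, 5))
    xs, ys = np.arange(5.0), np.arange(4.0)
    m = ResponseMap("m", 0, xs, ys, values)
    dense = interpolate_map(m, px_per_deg=3)

    def two_pass(x, y):
        i = min(int(np.floor(x)), 3)
        j = min(int(np.floor(y)), 2)
        fx, fy = x - i, y - j
        top = values[j, i] * (1 - fx) + values[j, i + 1] * fx
        bot = values[j + 1, i] * (1 - fx) + values[j + 1, i + 1] * fx
        return top * (1 - fy) + bot * fy

    for xi, x in enumerate(dense.xs):
        for yi, y in enumerate(dense.ys):
            assert dense.values[yi, xi] == pytest.approx(two_pass(x, y),
                                                         abs=1e-10)


def test_scale_map_constant_and_clipping(rng):
    assert np.all(scale_map(np.full((4, 4), 3.0)) == 0.5)
    v = rng.normal(size=1000).reshape(20, 50)
    scaled = scale_map(v)
    assert scaled.min() == 0.0 and scaled.max() == 1.0
    lo, hi = np.percentile(v, [0.5, 99.5])
    inside = (v > lo) & (v < hi)
    assert np.allclose(scaled[inside], (v[inside] - lo) / (hi - lo))
    # monotone
    flat_v, flat_s = v.ravel(), scaled.ravel()
    order = np.argsort(flat_v)
    assert np.all(np.diff(flat_s[order]) >= 0)


def test_temporal_maps_partition_total_count(small_session):
    s = small_session
    sid = s["scenes"][0].scene_id
    tm = temporal_maps(s["record"], s["protocol"], sid, 0,
                       s["array"].rf_center)
    assert len(tm) == 5
    total = build_scene_response_map(s["record"], s["protocol"], sid, 0,
                                     s["array"].rf_center, (50.0, 250.0))
    summed = sum(m.values * 0.040 for m in tm)
    assert np.allclose(summed, total.values * 0.200, atol=1e-9)


def test_eyes_activity_precedes_face_activity():
    """Per-bin oracle maps: the eye-region coordinate becomes active in an
    earlier 40 ms bin than a face coordinate away from the eyes."""
    face = scenes.Region("face", Ellipse((0.0, 0.0), 1.6, 2.0))
    eyes = scenes.Region("eyes", Ellipse((0.0, 1.5), 0.9, 0.3))
    scene = scenes.SceneSpec("fe", [face, eyes], "intact")
    cell = simulator.FaceCellModel(rf_center_deg=RF, rf_sigma_deg=0.5,
                                   baseline_hz=5.0)
    protocol = scenes.make_protocol(9, 1.0, RF, [scene], reps=5, seed=0)
    bins = [(t0, t0 + 40.0) for t0 in np.arange(50.0, 250.0, 40.0)]
    maps = [oracle_scene_response_map(cell, protocol, scene, RF, w)
            for w in bins]

    def first_active(coord, thresh=7.0):
        for b, m in enumerate(maps):
            ix = int(np.argmin(np.abs(m.xs - coord[0])))
            iy = int(np.argmin(np.abs(m.ys - coord[1])))
            if m.values[iy, ix] > thresh:
                return b
        return len(maps)

    assert first_active((0.0, 1.5)) < first_active((0.0, -1.0))


def test_population_map_mean_and_grid_check(rng):
    xs, ys = np.arange(3.0), np.arange(3.0)
    maps = [ResponseMap("s", ch, xs, ys, rng.normal(size=(3, 3)))
            for ch in range(3)]
    pop = population_map(maps)
    assert np.allclose(pop.values,
                       np.mean([m.values for m in maps], axis=0))
    bad = ResponseMap("s", 9, xs + 1, ys, maps[0].values)
    with pytest.raises(ValueError):
        population_map(maps + [bad])


def test_composite_constructed_inputs():
    xs, ys = np.arange(3.0), np.arange(3.0)
    base = 5.0
    low = {th: ResponseMap("s", 0, xs, ys, np.full((3, 3), base - 1.0))
           for th in (0.0, 90.0, 180.0, 270.0)}
    comp = composite_orientation_map(low, base)
    assert comp.masked.all()
    winner = dict(low)
    winner[90.0] = ResponseMap("s", 0, xs, ys, np.full((3, 3), base + 1.0))
    comp = composite_orientation_map(winner, base)
    assert not comp.masked.any()
    assert np.all(comp.best_orientation_deg == 90.0)


def test_composite_mismatched_grids_rejected():
    xs, ys = np.arange(3.0), np.arange(3.0)
    maps = {0.0: ResponseMap("s", 0, xs, ys, np.ones((3, 3))),
            90.0: ResponseMap("s", 0, xs + 1, ys, np.ones((3, 3)))}
    with pytest.raises(ValueError):
        composite_orientation_map(maps, 1.0)


def test_orientation_maps_peak_at_implied_face(small_session):
    """Simulated spikes: each orientation's map argmax lands near that
    orientation's implied-face anchor."""
    array = simulator.make_array(2, center=RF, seed=21)
    scene_set = scenes.make_scene_set("body_orientations", 1, seed=3)
    protocol = scenes.make_protocol(9, 2.0, RF, scene_set, reps=8, seed=4)
    record = simulator.simulate_session(array, protocol, scene_set, seed=5)
    hits = 0
    for scene in scene_set:
        m = build_scene_response_map(record, protocol, scene.scene_id,
                                     "population", RF)
        anchor = scene.regions[0].implied_face
        cx, cy = m.argmax_coord()
        if np.hypot(cx - anchor[0], cy - anchor[1]) <= 2.0:
            hits += 1
    assert hits >= 7   # of 8 orientations
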