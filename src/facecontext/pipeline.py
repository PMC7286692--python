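"""End-to-end pipeline: simulate -> map-rf -> map-scenes -> region-stats ->
orientation-map -> rsa, with a manifest of every artifact written.

Stages are individually callable (the CLI exposes them as subcommands) and
share a seeded generator hierarchy: one master seed spawns named per-stage
streams, so a stage can be re-run in isolation and the full run is
reproducible byte-for-byte from (config, seed) alone.  Tables are CSV,
configs and the manifest JSON, optional renderings PNG.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import mapping, region_stats, response_maps, rsa, scenes, simulator
from .config import RunConfig, validate_config

STAGES = ("simulate", "map-rf", "map-scenes", "region-stats",
          "orientation-map", "rsa")


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seed(master_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _gains(config: RunConfig) -> dict:
    g = dict(simulator.DEFAULT_GAINS)
    g["context_implied_face"] = config.context_gain_fraction * g["face"]
    return g


def build_array(config: RunConfig, seed: int) -> simulator.ArrayModel:
    return simulator.make_array(
        n_channels=config.n_channels, center=config.rf_center,
        rf_sigma_deg=config.rf_sigma_deg, seed=seed,
        baseline_hz=config.baseline_hz, gains=_gains(config))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, returning (and writing) the run manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    manifest = {"config": json.loads(config.to_json()), "stages": {},
                "artifacts": {}, "versions": {"numpy": np.__version__,
                                              "pandas": pd.__version__}}
    state = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(outdir, manifest)
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3),
                                     "files": [f.name for f in files]}
        for f in files:
            manifest["artifacts"][f.name] = _sha256(f)
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path, state: dict):
    seed = _stage_seed(config.seed, "simulate")
    array = build_array(config, seed)
    scene_list = []
    for i, arch in enumerate(config.archetypes):
        n = 1 if arch == "body_orientations" else config.n_exemplars
        scene_list.extend(scenes.make_scene_set(arch, n, seed + 17 * (i + 1)))
    protocol = scenes.make_protocol(
        config.grid_shape, config.spacing_deg, array.rf_center, scene_list,
        config.reps, seed + 1)
    record = simulator.simulate_session(array, protocol, scene_list, seed + 2)
    state.update(array=array, scenes=scene_list, protocol=protocol,
                 record=record)
    files = [outdir / "events.csv", outdir / "spikes.csv",
             outdir / "scenes.json"]
    protocol.to_csv(files[0])
    record.to_csv(files[1])
    scenes.save_scenes(files[2], scene_list)
    return files


def stage_map_rf(config: RunConfig, outdir: Path, state: dict):
    seed = _stage_seed(config.seed, "map-rf")
    array = state["array"]
    record, protocol, _ = simulator.simulate_probe_session(
        array, grid_shape=9, spacing_deg=1.0, grid_center_deg=(0.0, 0.0),
        reps=max(config.reps, 8), seed=seed)
    grids = [mapping.probe_response_grid(record, protocol, ch)
             for ch in record.channels]
    rows = []
    for ch, grid in zip(record.channels, grids):
        fit = mapping.fit_rf_gaussian(grid)
        rows.append({"channel": ch, "x_deg": fit.centroid_deg[0],
                     "y_deg": fit.centroid_deg[1],
                     "sigma_x_deg": fit.sigma_deg[0],
                     "sigma_y_deg": fit.sigma_deg[1],
                     "amplitude_hz": fit.amplitude_hz,
                     "offset_hz": fit.offset_hz, "goodness": fit.goodness})
    pop = mapping.population_rf(grids)
    state["rf_fits"] = pd.DataFrame(rows)
    files = [outdir / "rf_fits.csv", outdir / "population_rf.csv"]
    state["rf_fits"].to_csv(files[0], index=False, float_format="%.6g")
    pop.to_frame().to_csv(files[1], float_format="%.6g")
    return files


def stage_map_scenes(config: RunConfig, outdir: Path, state: dict):
    array, protocol, record = state["array"], state["protocol"], state["record"]
    rf_center = array.rf_center
    files = []
    state["scene_maps"] = {}
    for scene in state["scenes"]:
        m = response_maps.build_scene_response_map(
            record, protocol, scene.scene_id, "population", rf_center,
            config.window_ms)
        state["scene_maps"][scene.scene_id] = m
        path = outdir / f"map_{scene.scene_id.replace(':', '_')}.csv"
        m.to_frame().to_csv(path, float_format="%.6g")
        files.append(path)
    return files


def stage_region_stats(config: RunConfig, outdir: Path, state: dict):
    array, protocol, record = state["array"], state["protocol"], state["record"]
    rf_center = array.rf_center
    occluded = [s for s in state["scenes"] if s.image_set == "occluded"]
    if not occluded:
        return []
    kw = dict(rf_center=rf_center, smooth_sigma_ms=config.smooth_sigma_ms,
              smooth_window_ms=config.smooth_window_ms)
    psth_occ = region_stats.region_psth(record, protocol, occluded,
                                        "occluder", **kw)
    psth_ctrl = region_stats.region_psth(record, protocol, occluded,
                                         "background_control", **kw)
    trace = region_stats.binwise_paired_tests(
        psth_occ.per_image, psth_ctrl.per_image, q=config.q,
        min_run=config.min_run_bins)
    files = [outdir / "psth_occluded.csv", outdir / "psth_control.csv",
             outdir / "significance_occluded_vs_control.csv"]
    psth_occ.to_frame().to_csv(files[0], index=False, float_format="%.6g")
    psth_ctrl.to_frame().to_csv(files[1], index=False, float_format="%.6g")
    trace.to_frame().to_csv(files[2], index=False, float_format="%.6g")
    state["significance"] = trace
    return files


def stage_orientation_map(config: RunConfig, outdir: Path, state: dict):
    array, protocol = state["array"], state["protocol"]
    rf_center = array.rf_center
    by_orientation = {}
    for scene in state["scenes"]:
        if scene.image_set != "body_orientations":
            continue
        th = float(scene.meta["orientation_deg"])
        by_orientation[th] = response_maps.oracle_scene_response_map(
            array, protocol, scene, rf_center, config.window_ms)
    if not by_orientation:
        return []
    comp = response_maps.composite_orientation_map(by_orientation,
                                                   config.baseline_hz)
    files = [outdir / "orientation_composite.csv"]
    comp.to_frame().to_csv(files[0], float_format="%.6g")
    state["composite"] = comp
    return files


def stage_rsa(config: RunConfig, outdir: Path, state: dict):
    seed = _stage_seed(config.seed, "rsa")
    fm = rsa.make_category_features(
        n_per_category=config.rsa_n_per_category,
        n_features=config.rsa_n_features,
        face_body_shared=config.rsa_face_body_shared, seed=seed)
    z = rsa.zscore_features(fm)
    sim = rsa.pair_similarity(z, "spearman")
    summary = rsa.within_between_summary(sim)
    null = rsa.label_permutation_test(sim, config.rsa_n_permutations,
                                      seed=seed + 1)
    files = [outdir / "rsa_within_between.csv", outdir / "rsa_null_bounds.csv"]
    summary.to_csv(files[0], float_format="%.6g")
    null.summary().to_csv(files[1], index=False, float_format="%.6g")
    state["rsa_null"] = null
    return files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "map-rf": stage_map_rf,
    "map-scenes": stage_map_scenes,
    "region-stats": stage_region_stats,
    "orientation-map": stage_orientation_map,
    "rsa": stage_rsa,
}
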