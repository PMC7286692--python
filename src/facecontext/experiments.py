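"""Seeded validation experiments for the whole pipeline.

Each function simulates data under known ground truth, runs the analysis
under test, and measures how well the injected structure is recovered:
receptive-field parameter recovery, response-map registration against the
noise-free drive-rate oracle, context-latency recovery, the qualitative
contextual-facilitation contrasts (occluded faces, objects above bodies,
the ceiling rule), exact oracles for the statistical engine, the
orientation-composite geometry, RSA permutation-null calibration and the
face-body merging construction, and byte-level pipeline determinism.

Problem sizes are scaled from the recorded sessions (28-32 channels) to a
handful of simulated channels; population pooling makes statistical power
depend mainly on image count and repetitions, which stay at session scale
(about 10 images, 5-10 repetitions per grid position, 9 x 9 grids).
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np

from . import mapping, region_stats, response_maps, rsa, scenes, simulator
from .config import RunConfig
from .pipeline import run_pipeline

RF_CENTER = (1.0, -0.5)


def _face_only_gains(gain_hz):
    return {"eyes": 0.0, "face": float(gain_hz),
            "context_implied_face": 0.0, "context_feet": 0.0}


def _session_array(n_channels=4, seed=0, **kw):
    return simulator.make_array(n_channels=n_channels, center=RF_CENTER,
                                seed=seed, **kw)


# ---------------------------------------------------------------------------
# receptive-field parameter recovery
# ---------------------------------------------------------------------------

def rf_recovery_experiment(n_runs: int = 50, seed: int = 0, reps: int = 10,
                           baseline_hz: float = 5.0, gain_hz: float = 40.0,
                           centroid_tol_deg: float = 0.25,
                           sigma_rel_tol: float = 0.20) -> dict:
    """Simulate probe sessions with known RF centre/width and check that the
    2D Gaussian fit recovers both."""
    rng = np.random.default_rng(seed)
    centroid_err, sigma_rel_err, ok = [], [], []
    for i in range(n_runs):
        center = tuple(rng.uniform(-1.5, 1.5, 2))
        sig = float(rng.uniform(0.8, 1.4))
        cell = simulator.FaceCellModel(
            rf_center_deg=center, rf_sigma_deg=sig, baseline_hz=baseline_hz,
            gains=_face_only_gains(gain_hz))
        array = simulator.ArrayModel([cell])
        record, protocol, _ = simulator.simulate_probe_session(
            array, grid_shape=9, spacing_deg=1.0, grid_center_deg=(0.0, 0.0),
            reps=reps, seed=seed * 1000 + i)
        fit = mapping.fit_rf_gaussian(
            mapping.probe_response_grid(record, protocol, 0),
            independent_sigma=False)
        ce = float(np.hypot(fit.centroid_deg[0] - center[0],
                            fit.centroid_deg[1] - center[1]))
        se = float(max(abs(fit.sigma_deg[0] - sig), abs(fit.sigma_deg[1] - sig)) / sig)
        centroid_err.append(ce)
        sigma_rel_err.append(se)
        ok.append(ce <= centroid_tol_deg and se <= sigma_rel_tol)
    return {"fraction_ok": float(np.mean(ok)), "n_runs": n_runs,
            "centroid_err_deg": np.asarray(centroid_err),
            "sigma_rel_err": np.asarray(sigma_rel_err)}


# ---------------------------------------------------------------------------
# response-map registration
# ---------------------------------------------------------------------------

DELTA_COORDS = ((2.0, 2.0), (-2.0, 4.0), (4.0, -2.0), (-4.0, -4.0), (2.0, -4.0))


def map_registration_experiment(seed: int = 0, n_seeds: int = 10,
                                reps: int = 20) -> dict:
    """Delta-responder scenes: a single face at a known off-centre image
    coordinate must reconstruct with its map argmax exactly there (no
    mirror/sign error), and the full map must correlate with the noise-free
    drive-rate oracle."""
    cell = simulator.FaceCellModel(
        rf_center_deg=RF_CENTER, rf_sigma_deg=0.6, baseline_hz=2.0,
        gains=_face_only_gains(60.0))
    array = simulator.ArrayModel([cell])
    scene_list = [
        scenes.SceneSpec(f"delta:{i}",
                         [scenes.Region("face", scenes.Ellipse(c, 0.8, 1.0))],
                         "intact")
        for i, c in enumerate(DELTA_COORDS)]
    exact, pearson = [], []
    for s in range(n_seeds):
        protocol = scenes.make_protocol(9, 2.0, RF_CENTER, scene_list, reps,
                                        seed + 100 + s)
        record = simulator.simulate_session(array, protocol, scene_list,
                                            seed + 200 + s)
        for delta_scene, c_true in zip(scene_list, DELTA_COORDS):
            m = response_maps.build_scene_response_map(
                record, protocol, delta_scene.scene_id, 0, RF_CENTER)
            exact.append(bool(np.allclose(m.argmax_coord(), c_true,
                                          atol=1e-9)))
            oracle = response_maps.oracle_scene_response_map(
                cell, protocol, delta_scene, RF_CENTER)
            r = np.corrcoef(m.values.ravel(), oracle.values.ravel())[0, 1]
            pearson.append(float(r))
    return {"exact_fraction": float(np.mean(exact)),
            "pearson_r": np.asarray(pearson),
            "pearson_min": float(np.min(pearson)),
            "n_maps": len(exact)}


# ---------------------------------------------------------------------------
# context-latency recovery
# ---------------------------------------------------------------------------

def context_latency_experiment(seed: int = 0, n_images: int = 12,
                               reps: int = 8, n_channels: int = 8) -> dict:
    """Face latency 95 ms vs context latency 130 ms: the region-PSTH
    half-max latency difference between intact-face and occluded-face
    regions should recover the injected 35 ms.

    Intact comparison scenes are built without eye regions so the measured
    face latency reflects the face drive rather than the earlier eye
    drive."""
    array = _session_array(n_channels, seed)
    intact = scenes.make_scene_set("intact", n_images, seed + 1,
                                   include_eyes=False)
    occluded = scenes.make_scene_set("occluded", n_images, seed + 2)
    all_scenes = intact + occluded
    protocol = scenes.make_protocol(9, 2.0, array.rf_center, all_scenes,
                                    reps, seed + 3)
    record = simulator.simulate_session(array, protocol, all_scenes, seed + 4)
    kw = dict(rf_center=array.rf_center)
    psth_face = region_stats.region_psth(record, protocol, intact, "face", **kw)
    psth_occ = region_stats.region_psth(record, protocol, occluded,
                                        "occluder", **kw)
    lat_face = region_stats.halfmax_latency(psth_face.mean)
    lat_occ = region_stats.halfmax_latency(psth_occ.mean)
    return {"face_latency_ms": lat_face, "occluded_latency_ms": lat_occ,
            "difference_ms": lat_occ - lat_face, "n_images": n_images}


# ---------------------------------------------------------------------------
# contextual-facilitation contrasts
# ---------------------------------------------------------------------------

def _session_traces(contrast: str, seed: int, reps: int, n_channels: int):
    array = _session_array(n_channels, seed)
    if contrast == "occluded_vs_control":
        scene_list = scenes.make_scene_set("occluded", 10, seed + 1)
        a_scenes = b_scenes = scene_list
        key_a, key_b, key_by = "occluder", "background_control", "label"
    elif contrast == "object_above_body_vs_elsewhere":
        scene_list = scenes.make_scene_set("face_swapped", 8, seed + 1)
        a_scenes = b_scenes = scene_list
        key_a, key_b, key_by = "object_atop_body", "object_control", "name"
    elif contrast == "face_above_body_vs_alone":
        full = scenes.make_scene_set("face_variants_x_body", 7, seed + 1)
        face_pairs = [s for s in full if s.meta.get("variant") == "face"]
        scene_list = face_pairs
        a_scenes = sorted([s for s in face_pairs if s.meta["with_body"]],
                          key=lambda s: s.meta["exemplar"])
        b_scenes = sorted([s for s in face_pairs if not s.meta["with_body"]],
                          key=lambda s: s.meta["exemplar"])
        key_a = key_b = "face_region"
        key_by = "name"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    protocol = scenes.make_protocol(9, 2.0, array.rf_center, scene_list,
                                    reps, seed + 2)
    record = simulator.simulate_session(array, protocol, scene_list, seed + 3)
    kw = dict(rf_center=array.rf_center)
    psth_a = region_stats.region_psth(record, protocol, a_scenes, key_a,
                                      key_by=key_by, **kw)
    psth_b = region_stats.region_psth(record, protocol, b_scenes, key_b,
                                      key_by=key_by, **kw)
    return psth_a.per_image, psth_b.per_image


def contrast_significance_experiment(contrast: str, n_sessions: int = 50,
                                     seed: int = 0, reps: int = 8,
                                     n_channels: int = 4, q: float = 0.05,
                                     min_run: int = 5) -> dict:
    """Fraction of seeded sessions in which the paired bin-wise tests find
    an FDR-significant window (>= min_run consecutive rejected bins)."""
    hits, latencies = [], []
    for i in range(n_sessions):
        a, b = _session_traces(contrast, seed + 1000 * (i + 1), reps,
                               n_channels)
        trace = region_stats.binwise_paired_tests(a, b, q=q, min_run=min_run)
        windows = trace.significant_windows
        hits.append(bool(windows))
        if trace.latency_ms is not None:
            latencies.append(trace.latency_ms)
    return {"significant_fraction": float(np.mean(hits)),
            "latencies_ms": np.asarray(latencies), "n_sessions": n_sessions}


def category_selectivity_experiment(seed: int = 0, n_channels: int = 8,
                                    reps: int = 10) -> dict:
    """Face vs non-face selectivity of the simulated array when isolated
    category images (face, hand, body, object) are presented within the
    activating region."""
    array = _session_array(n_channels, seed)
    cats = scenes.make_category_probe_scenes()
    scene_list = list(cats.values())
    protocol = scenes.make_protocol(1, 2.0, array.rf_center, scene_list,
                                    reps, seed + 1)
    record = simulator.simulate_session(array, protocol, scene_list, seed + 2)
    tuning = mapping.category_tuning(
        record, protocol, {s.scene_id: name for name, s in cats.items()})
    nonface = tuning.means[["hand", "body", "object"]].mean(axis=1).clip(lower=0.0)
    idx = np.array([mapping.selectivity_index(f, nf)
                    for f, nf in zip(tuning.means["face"], nonface)])
    return {"indices": idx, "mean": float(idx.mean()),
            "std": float(idx.std(ddof=1)), "n_channels": n_channels}


# ---------------------------------------------------------------------------
# statistical-engine oracles
# ---------------------------------------------------------------------------

def bh_stepup_reference(pvals, q: float) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up: scan ranks one by one."""
    p = np.asarray(pvals, float).copy()
    p[~np.isfinite(p)] = 1.0
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k = rank
    mask = np.zeros(m, bool)
    if k:
        mask[order[:k]] = True
    return mask


def wilcoxon_exact_reference(a, b) -> float:
    """Exact two-sided signed-rank p-value by enumerating all sign
    assignments of the ranked absolute differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    w_all = np.array([float(np.sum(np.array(signs) * ranks))
                      for signs in itertools.product((0, 1), repeat=n)])
    p_low = np.mean(w_all <= w_obs)
    p_high = np.mean(w_all >= w_obs)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def stats_oracle_experiment(seed: int = 0, n_pvectors: int = 1000,
                            n_wilcoxon: int = 200,
                            n_null_sessions: int = 200) -> dict:
    """Exact agreement of the statistical engine with brute-force oracles,
    plus the rejection rate under an exchangeable (no-effect) null."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pvectors):
        m = int(rng.integers(5, 200))
        scale = rng.choice([0.05, 0.3, 1.0])
        p = np.minimum(rng.uniform(size=m) * scale, 1.0)
        q = float(rng.choice([0.01, 0.05, 0.1]))
        if np.array_equal(region_stats.bh_fdr(p, q), bh_stepup_reference(p, q)):
            agree += 1
    wilc_diff = []
    for _ in range(n_wilcoxon):
        n = int(rng.integers(4, 11))
        a = rng.normal(0.3, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        wilc_diff.append(abs(region_stats.wilcoxon_check(a, b)
                             - wilcoxon_exact_reference(a, b)))
    any_rejection = []
    for _ in range(n_null_sessions):
        lam = 20.0 / 1000.0 * 32
        counts_a = rng.poisson(lam, (8, 300)) / 32 * 1000.0
        counts_b = rng.poisson(lam, (8, 300)) / 32 * 1000.0
        a = np.apply_along_axis(region_stats.smooth_trace, 1, counts_a)
        b = np.apply_along_axis(region_stats.smooth_trace, 1, counts_b)
        trace = region_stats.binwise_paired_tests(a, b)
        any_rejection.append(bool(trace.rejected.any()))
    return {"bh_agreement": agree / n_pvectors,
            "wilcoxon_max_abs_diff": float(np.max(wilc_diff)),
            "null_any_rejection_fraction": float(np.mean(any_rejection)),
            "n_pvectors": n_pvectors, "n_null_sessions": n_null_sessions}


# ---------------------------------------------------------------------------
# orientation composites
# ---------------------------------------------------------------------------

def orientation_composite_experiment(seed: int = 0, n_channels: int = 4) -> dict:
    """Composite orientation map vs the nearest-implied-face geometric
    oracle, built from noise-free oracle maps pushed through the map
    machinery (registration, grid assembly, argmax, baseline mask)."""
    array = _session_array(n_channels, seed)
    scene_set = scenes.make_scene_set("body_orientations", 1, seed + 1)
    protocol = scenes.make_protocol(9, 2.0, array.rf_center, scene_set,
                                    reps=5, seed=seed + 2)
    maps, anchors = {}, {}
    for s in scene_set:
        th = float(s.meta["orientation_deg"])
        maps[th] = response_maps.oracle_scene_response_map(
            array, protocol, s, array.rf_center)
        anchors[th] = s.regions[0].implied_face
    comp = response_maps.composite_orientation_map(maps,
                                                   array.channels[0].baseline_hz)
    X, Y = np.meshgrid(comp.xs, comp.ys)
    orients = np.asarray(comp.orientations)
    dist = np.stack([np.hypot(X - anchors[th][0], Y - anchors[th][1])
                     for th in orients])
    predicted = orients[np.argmin(dist, axis=0)]
    unmasked = ~comp.masked
    agreement = float(np.mean(
        comp.best_orientation_deg[unmasked] == predicted[unmasked]))
    return {"agreement": agreement, "n_unmasked": int(unmasked.sum()),
            "n_points": int(comp.masked.size)}


# ---------------------------------------------------------------------------
# RSA calibration and face-body merging
# ---------------------------------------------------------------------------

def rsa_calibration_experiment(n_runs: int = 500, n_permutations: int = 500,
                               seed: int = 0, n_per_category: int = 10,
                               n_features: int = 40) -> dict:
    """Under exchangeable features the label-shuffle 2.5-97.5% bounds should
    cover the observed face-vs-body similarity in about 95% of runs."""
    covered = []
    for i in range(n_runs):
        fm = rsa.make_category_features(
            n_per_category=n_per_category, n_features=n_features,
            category_scale=0.0, face_body_shared=0.0, seed=seed + 2 * i)
        null = rsa.label_permutation_test(fm, n_permutations,
                                         seed=seed + 2 * i + 1)
        key = "faces_vs_bodies"
        covered.append(null.lower[key] <= null.observed[key]
                       <= null.upper[key])
    return {"coverage": float(np.mean(covered)), "n_runs": n_runs}


def rsa_merging_experiment(seed: int = 0,
                           shared_weights=(0.0, 1.0, 2.0, 3.0),
                           n_permutations: int = 500) -> dict:
    """Face-body between-category similarity should grow monotonically with
    the shared latent weight and cross the 97.5% label-shuffle bound once
    the shared component is strong."""
    observed, upper = [], []
    for lam in shared_weights:
        fm = rsa.make_category_features(face_body_shared=lam, seed=seed)
        null = rsa.label_permutation_test(fm, n_permutations, seed=seed + 1)
        observed.append(null.observed["faces_vs_bodies"])
        upper.append(null.upper["faces_vs_bodies"])
    observed = np.asarray(observed)
    return {"shared_weights": np.asarray(shared_weights),
            "observed": observed, "upper": np.asarray(upper),
            "monotone": bool(np.all(np.diff(observed) > 0)),
            "crossed": bool(observed[-1] > upper[-1])}


def weight_shuffle_multiset_check(seed: int = 0) -> dict:
    """Weight shuffling must preserve each layer's weight multiset exactly."""
    net = rsa.ToyReluNet([12, 8, 6], seed=seed)
    shuffled = net.with_shuffled_weights(np.random.default_rng(seed + 1))
    preserved = all(
        np.array_equal(np.sort(w0.ravel()), np.sort(w1.ravel()))
        and not np.array_equal(w0, w1)
        for w0, w1 in zip(net.weights, shuffled.weights))
    return {"preserved": bool(preserved), "n_layers": len(net.weights)}


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def determinism_experiment(seed: int = 0, base_dir="scratch/determinism") -> dict:
    """Two pipeline runs with identical config+seed must produce
    byte-identical tabular outputs."""
    base = Path(base_dir)
    digests = []
    for run in ("a", "b"):
        cfg = RunConfig(seed=seed, outdir=str(base / run), n_channels=2,
                        n_exemplars=3, reps=5, rsa_n_permutations=100)
        run_pipeline(cfg)
        files = sorted((base / run).glob("*.csv"))
        digests.append({f.name: f.read_bytes() for f in files})
    identical = (digests[0].keys() == digests[1].keys()
                 and all(digests[0][k] == digests[1][k] for k in digests[0]))
    return {"identical": bool(identical), "n_files": len(digests[0])}
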