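# facecontext

Analysis pipeline for studying **contextual face responses** in visual
cortex: how face-selective neurons respond not only to faces, but to parts
of an image where a face *ought* to be — for example just above a body whose
face is occluded.

The package is aimed at systems neuroscientists analysing multi-electrode
recordings from face-selective sites (e.g. macaque face patches PL/ML)
during large-scene presentation experiments, and at anyone who wants to
prototype or validate such analyses without recordings: a first-class
synthetic spike generator emulates contextually tuned face cells, so every
stage can be exercised and verified against known ground truth.

## What it computes

**Receptive-field mapping.** Small face probes are flashed over a grid;
per-position responses are the baseline-subtracted mean rate (80–250 ms
after onset minus the pooled 0–30 ms rate).  A 2D Gaussian

    r(x, y) = r0 + A · exp(−(x−x0)²/2σx² − (y−y0)²/2σy²)

is fit to each channel's 9 × 9 response grid (centroid, 1-σ widths); the
population RF is the mean grid.  Category selectivity uses the bounded index
`(r1 − r2)/(r1 + r2)`.

**Scene response maps.** A 16° × 16° scene presented with its centre at
grid position *g* puts image coordinate **c = r − g** over the RF centre
*r*.  Averaging windowed rates over repetitions of each position therefore
yields a map indexed by *image* coordinate — which part of the scene drove
the cells when it lay over the RF.  Maps come with bilinear interpolation,
0.5–99.5 percentile display scaling, 40 ms temporal bins, and composite
maps giving the best body orientation per grid point.

**Region statistics.** Presentations whose RF-centre image coordinate falls
inside a labeled region (face, occluded face, control, …) are pooled into
per-image PSTHs (1 ms bins, Gaussian-smoothed over a 20 ms window).  Paired
two-sided t-tests run per bin across images with Benjamini–Hochberg FDR
correction at q = 0.05; response latency is the start of the first
significant run of ≥ 5 bins, verified with exact Wilcoxon signed-rank tests.

**Representational similarity.** Image-feature matrices (pixels, toy or
plug-in network layers) are z-scored per unit and compared with Spearman
rank correlations per image pair, summarized within/between categories,
embedded with classical MDS on squared Euclidean distances, and tested
against two permutation nulls: label shuffling of non-face images (2.5/97.5
percentile bounds over 2500 permutations) and distribution-preserving
weight shuffling of the extractor network (500 permutations).

**Simulator.** Channels are face cells with Gaussian RFs (σ ≈ 0.5–1.5°,
near fixation) and additive drives — eyes (latency ≈ 70 ms), intact face
(≈ 95 ms), and context at a body's *implied-face anchor* (≈ 130 ms, weaker)
— through a unit-peak kernel, with a ceiling rule (context is suppressed
when an intact face is present) and inversion attenuation.  Spikes are an
inhomogeneous Poisson process.  See `docs/methods.md` for the model.

## Worked example

```python
from facecontext import (make_array, make_scene_set, make_protocol,
                         simulate_session, build_scene_response_map,
                         region_psth, binwise_paired_tests)

array = make_array(n_channels=4, center=(1.0, -0.5), seed=0)
scenes = make_scene_set("occluded", 10, seed=1)          # occluded-face scenes
protocol = make_protocol(9, 2.0, array.rf_center, scenes, reps=8, seed=2)
record = simulate_session(array, protocol, scenes, seed=3)

m = build_scene_response_map(record, protocol, scenes[0].scene_id,
                             "population", array.rf_center)
print("map peak (image coords):", m.argmax_coord())
print("implied face anchor:    ", scenes[0].regions_by("body")[0].implied_face)

occ = region_psth(record, protocol, scenes, "occluder", array.rf_center)
ctl = region_psth(record, protocol, scenes, "background_control", array.rf_center)
sig = binwise_paired_tests(occ.per_image, ctl.per_image)
print("significant windows (start_bin_ms, n_bins):", sig.significant_windows)
print("response latency:", sig.latency_ms, "ms")
```

prints

```
map peak (image coords): (0.0, 0.0)
implied face anchor:     (0.0, 0.0)
significant windows (start_bin_ms, n_bins): [(134, 128), (269, 8), (280, 5), (286, 37), (335, 9)]
response latency: 134.0 ms
```

The response map of an occluded-face scene peaks exactly at the implied-face
anchor — the cells respond to where the face ought to be — and the
occluded-face vs control contrast becomes significant from 134 ms, ~35 ms
later than the intact-face latency the simulator injects (95 ms plus the
kernel rise), reproducing the delayed contextual response.

The numbered drivers under `analysis/` walk through the full study
(`01_receptive_fields.py` … `05_rsa_category_similarity.py`); each writes
its tables under `results/` and prints what it found.  The `facecontext`
CLI (`simulate`, `map-rf`, `map-scenes`, `region-stats`, `orientation-map`,
`rsa`, `run-all`) runs the same stages from configuration files.

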