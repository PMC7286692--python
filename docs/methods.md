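# Methods

## The face-cell model

Each simulated channel is a face-selective unit with a 2D Gaussian
receptive field (RF) and a set of additive, latency-shifted drives.  The
instantaneous rate for a scene presented with its centre at grid position
*g* is

    rate(t) = baseline + Σ_d  gain_d · strength_d · att_d · G(|loc_d + g − r|) · k(t − latency_d)

where `G(d) = exp(−d²/2σ²)` is the RF profile evaluated at the drive
location translated by the grid position, `r` is the RF centre, and `k` is
a unit-peak difference-of-exponentials kernel.  Drives and defaults:

| drive                  | location                      | gain (Hz) | latency (ms) |
|------------------------|-------------------------------|-----------|--------------|
| `eyes`                 | eye-region centre             | 25        | 70           |
| `face`                 | face-region centre            | 40        | 95           |
| `context_implied_face` | body's implied-face anchor    | 16        | 130          |
| `context_feet`         | body's feet anchor            | 8         | 130          |

Other parameters: `rf_sigma_deg` 1.0 (activating regions 1–3° wide),
`baseline_hz` 5, RF centres jittered by 0.15° around a common array centre
near fixation, kernel rise 10 ms / decay 150 ms, and an area-level latency
offset so a posterior (PL-like) array can lead a middle (ML-like) one.

**Kernel.** Any smooth unimodal kernel would serve; the decay is set to
150 ms so that responses are *sustained* across the 100–250 / 150–300 ms
analysis windows, as real face-patch responses are (a short ~40 ms decay
would leave the second half of those windows empty of signal, which is
inconsistent with windows chosen to average over them).

**Context rules.** The context drive is anchored to the *implied-face*
point — where a face ought to be given the body's position and orientation
— not to body-mask overlap; this is what makes the composite-orientation
prediction (winner = nearest implied-face anchor) testable.  Two
qualitative rules of contextual facilitation are built in:

* *ceiling rule* — the implied-face drive is suppressed whenever an intact
  face region covers the anchor, so bodies facilitate only when the
  presence of a face is ambiguous;
* *inversion attenuation* (default 0.5) — applied to the sustained context
  and ambiguous-face drives of inverted configurations, but only during
  the kernel rise for intact faces, giving a brief upright/inverted
  difference for real faces and a sustained one for face-shaped noise.

Face-shaped noise patches and outlines carry a weak face-like drive
(`ambiguous_face_strength`, default 0.3 of the face gain): face-typical
shape alone drives the cells above baseline even without a body.  The
context gain (0.4 of the face gain) is a free parameter exposed in the
configuration; nothing downstream depends on its exact value beyond the
power of the contrast tests.

Spikes are drawn as an inhomogeneous Poisson process (1 ms bins, uniform
jitter within a bin) on top of one homogeneous session-wide baseline, so
overlapping presentation epochs superpose additively.  No refractoriness is
modelled: every downstream statistic is a windowed mean or count, which is
insensitive to spike-interval structure.

## Scenes and protocols

Scenes are parametric shape layouts, not photographs: the analysis consumes
only the *relational* structure (face above body, occluders over faces,
matched with/without-body pairs, bodies at 45°-step orientations), which
the seven archetype factories preserve.  Coordinates are visual degrees,
fixation at the origin, x rightward, y upward; image coordinates are
relative to the image centre; rasters store row 0 at top.  Region positions
snap to a 2° lattice so that presentation grids sample region centres
exactly.  Backgrounds are brown noise (1/f² spectrum; verified slope −2.5
to −1.5); rasterization uses 2× supersampled coverage (areas within ~2% of
analytic at the default 4 px/°).

Protocols follow the recording design: images presented over a 17 × 17 grid
at 1° spacing or a 9 × 9 grid at 2° spacing centred on the population RF,
100 ms ON / 200 ms OFF, three images per trial, each (scene, position) pair
repeated 5–10 times in seeded random order.

## Analysis choices

* **Probe responses** are mean rates over 80–250 ms minus the baseline
  (first 30 ms) rate.  By default the baseline is pooled across all
  presentations of a channel before subtraction: the spontaneous rate is
  stationary, so pooling estimates the same quantity as per-presentation
  pairing while avoiding the ~4 Hz/position variance a 10-repetition ×
  30 ms count carries; the paired variant remains available
  (`baseline="paired"`).
* **RF fits** use bounded nonlinear least squares with multi-start
  initialisation (grid argmax and positive-mass centroid), missing
  positions excluded from the loss; noiseless grids round-trip to optimizer
  precision.  Both independent-σ and isotropic fits are supported
  (independent by default).
* **Map registration**: the rate at grid position *g* is assigned to image
  coordinate `c = r − g` (the part of the image over the RF centre).  This
  sign convention is pinned by an oracle constructor that pushes the
  noise-free drive-rate model through the identical code path.  Windows may
  overlap the next presentation's epoch (e.g. 100–250 ms extends past the
  100 ms ON); no correction is applied — any contamination is the
  simulator's to emulate.
* **Interpolation/scaling**: bilinear between nodes with dense axes chosen
  so nodes are preserved bit-exactly and nothing is extrapolated; display
  scaling clips at the per-image 0.5/99.5 percentiles of the dense map (a
  constant map renders mid-scale).  Temporal maps use half-open,
  onset-aligned 40 ms bins.
* **Region PSTHs**: a presentation contributes to a region's trace iff
  `c = r − g` lies inside the region shape; traces are averaged within
  image, summarized across images (t-based 95% band), and smoothed last
  (Gaussian, 20 ms window, σ = 5 ms).
* **Statistics**: per-1 ms-bin two-sided paired t-tests across images,
  Benjamini–Hochberg step-up at q = 0.05 (NaN p-values count toward the
  family but are never rejected).  A "significant window" is a run of ≥ 5
  consecutive rejected bins (the minimum run length is configurable);
  latency is the first such run's start.  The Wilcoxon verification uses
  the exact null distribution for ≤ 25 untied non-zero differences and the
  normal approximation otherwise.  Where an absolute latency of a smooth
  trace is needed (the context-delay recovery), the half-max crossing of
  the trial-averaged trace is used: it is symmetric under the smoothing and
  cancels the kernel rise between conditions.
* **Composites**: per grid point the orientation with maximal response wins
  (ties to the lowest orientation); points with all orientations at or
  below baseline are masked.
* **RSA**: per-unit z-scoring drops zero-variance units (count logged);
  Spearman is rank-transform-then-Pearson; within-category means exclude
  self-pairs; MDS is classical (Torgerson) double-centering of squared
  Euclidean distances — deterministic, matching the squared-distance input,
  rather than stress-minimizing MDS.  Label shuffling keeps face labels
  fixed and permutes only non-face labels; because every non-face image
  pairs with every face, the face-vs-category statistic reduces exactly to
  a mean over per-image mean-similarity-to-faces, which is how it is
  computed.  Weight shuffling permutes each layer's weights in place
  (multiset preserved exactly), simulating an untrained network; the
  pretrained network of interest is a plug-in behind the extractor
  interface, and all built-in analyses run on pixel layers,
  random-projection layers, or tiny seeded toy networks.

## What the synthetic generator emulates — and what it does not

Emulated: Poisson-like spiking around a baseline; small Gaussian RFs near
fixation; face-evoked responses at ~95 ms and eye-specific responses at
~70 ms; implied-face (context) responses ~35 ms slower and weaker; weaker
feet-context responses; the ceiling effect; transient-vs-sustained
inversion effects; PL-before-ML latency ordering; uniform tuning across an
array's channels.

Not emulated: real scene statistics (regions are flat parametric patches),
adaptation and refractoriness, trial-to-trial rate correlations, eye
movements and microsaccades, reward artifacts, spike-sorting noise, and
channel heterogeneity beyond RF-centre jitter.  Passing tests therefore
demonstrate that the *analysis* recovers what the model injects under
realistic counting noise — not that the model captures everything real
recordings contain.

## Validation problem sizes

The seeded validation experiments (tests and `scripts/acceptance.py`) use
session-scale image counts and repetitions — 9 × 9 grids at 2° spacing,
8–12 images per set, 5–10 repetitions per (scene, position) — with 4–8
simulated channels rather than the 28–32 sites of a chronic array:
population pooling makes the contrast power depend mainly on image count
and repetitions, and the smaller channel count keeps a full 50-session
experiment in tens of seconds.  The RF-recovery experiment uses 9 × 9 probe
grids at 1° spacing, 10 repetitions, baseline 5 Hz and gain 40 Hz; the RSA
calibration uses 10 images per category × 6 categories with 500
permutations per run.

## Known limitations

* The latency-from-significance estimate inherits the FDR threshold: when
  many bins are truly significant the step-up threshold loosens and
  correlated noise in the pre-response epoch can occasionally produce an
  early spurious run; the half-max latency is the robust choice for timing
  differences.
* Percentile display scaling is computed on the interpolated map (matching
  figure rendering); computing it on grid nodes gives slightly different
  bounds.
* Classical MDS assumes the squared-distance Gram matrix is close to
  positive semi-definite; strongly non-Euclidean similarity structures
  would need a stress-based embedding instead.
* The weight-shuffle null requires an extractor exposing mutable per-layer
  weights; it does not apply to the pixel layer.
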