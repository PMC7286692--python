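"""Region-conditioned PSTHs and bin-wise FDR-corrected statistics.

A presentation contributes to a region's peristimulus time histogram iff the
image coordinate over the RF centre (``c = r - g``) lies inside the region.
Traces are averaged within image first, then summarized across images
(mean and 95% confidence band); Gaussian smoothing (20 ms window, sigma
5 ms) is applied last.  Paired two-sided t-tests run per 1 ms bin across
images, Benjamini-Hochberg corrected at q = 0.05; response latency is the
start of the first FDR-significant run of at least ``min_run`` consecutive
bins.  Significant effects can be verified with Wilcoxon signed-rank tests
(exact distribution for small n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .response_maps import image_coordinate
from .scenes import PresentationProtocol, SceneSpec
from .simulator import SpikeRecord


class EmptyRegionError(ValueError):
    """Raised when no presentation places the region over the RF centre."""


class InsufficientPairsError(ValueError):
    """Raised when fewer than 3 paired images are available for testing."""


@dataclass
class PSTH:
    """Per-image rate traces (Hz) for one region condition.

    ``per_image[i]`` is image i's trace on 1 ms bins, averaged over
    contributing presentations and channels, then smoothed.  The confidence
    band is the t-based 95% interval across images."""

    time_ms: np.ndarray
    per_image: np.ndarray
    image_ids: list
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    smoothing: tuple   # (window_ms, sigma_ms)

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"bin_ms": self.time_ms, "image": img,
                              "rate_hz": tr})
                for img, tr in zip(self.image_ids, self.per_image)]
        return pd.concat(rows, ignore_index=True)


@dataclass
class SignificanceTrace:
    """Per-bin p-values with BH-FDR rejections, runs, and latency."""

    pvals: np.ndarray
    rejected: np.ndarray
    runs: list                 # (start_bin, length) of maximal rejected runs
    latency_ms: float | None   # start of first run of >= min_run bins
    q: float
    min_run: int

    @property
    def significant_windows(self):
        return [(s, l) for s, l in self.runs if l >= self.min_run]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_ms": np.arange(self.pvals.size),
                             "p": self.pvals, "rejected": self.rejected})


def smooth_trace(trace, sigma_ms: float = 5.0, window_ms: float = 20.0):
    """Gaussian smoothing truncated to the stated sliding window."""
    truncate = (window_ms / 2.0) / sigma_ms
    return ndimage.gaussian_filter1d(np.asarray(trace, float), sigma_ms,
                                     truncate=truncate, mode="nearest")


def region_psth(record: SpikeRecord, protocol: PresentationProtocol,
                scenes, region_key: str, rf_center, key_by: str = "label",
                channels=None, epoch_ms: int = 350,
                smooth_sigma_ms: float = 5.0, smooth_window_ms: float = 20.0,
                smooth: bool = True) -> PSTH:
    """Population PSTH of presentations whose RF-centre image coordinate
    falls inside the named region, per image.

    Scenes lacking the region (or never presenting it over the RF) simply
    contribute no image; if no scene contributes at all an
    :class:`EmptyRegionError` is raised."""
    if channels is None:
        channels = record.channels
    ev = protocol.events
    per_image, image_ids = [], []
    for scene in scenes:
        regions = scene.regions_by(region_key, by=key_by)
        if not regions:
            continue
        sel = ev["scene_id"] == scene.scene_id
        if not sel.any():
            continue
        sub = ev[sel]
        cx, cy = image_coordinate(rf_center, sub["grid_x"].to_numpy(float),
                                  sub["grid_y"].to_numpy(float))
        inside = np.zeros(len(sub), bool)
        for r in regions:
            inside |= r.shape.contains(cx, cy)
        if not inside.any():
            continue
        onsets = sub["onset_ms"].to_numpy(float)[inside]
        trace = np.zeros(epoch_ms)
        for ch in channels:
            for onset in onsets:
                trace += record.binned_counts(ch, onset, epoch_ms)
        trace = trace / (onsets.size * len(channels)) * 1000.0
        if smooth:
            trace = smooth_trace(trace, smooth_sigma_ms, smooth_window_ms)
        per_image.append(trace)
        image_ids.append(scene.scene_id)
    if not per_image:
        raise EmptyRegionError(
            f"no presentation places region {region_key!r} over the RF centre")
    per_image = np.asarray(per_image)
    mean = per_image.mean(axis=0)
    n = per_image.shape[0]
    if n > 1:
        sem = per_image.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
    else:
        sem, tcrit = np.zeros_like(mean), 0.0
    return PSTH(np.arange(epoch_ms, dtype=float), per_image, image_ids, mean,
                mean - tcrit * sem, mean + tcrit * sem,
                (smooth_window_ms, smooth_sigma_ms))


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask.  NaN p-values are treated
    as 1 (never rejected) but still count toward the family size."""
    p = np.asarray(pvals, float).copy()
    p[~np.isfinite(p)] = 1.0
    m = p.size
    order = np.argsort(p, kind="mergesort")
    thresh = q * (np.arange(m) + 1) / m
    below = p[order] <= thresh
    if not below.any():
        return np.zeros(m, bool)
    cutoff = p[order][np.nonzero(below)[0].max()]
    return p <= cutoff


def _runs(mask):
    """Maximal runs of consecutive True values as (start, length)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return []
    d = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def binwise_paired_tests(traces_a, traces_b, q: float = 0.05,
                         min_run: int = 5) -> SignificanceTrace:
    """Two-sided paired t-test per 1 ms bin across images, BH-FDR corrected.

    ``traces_a`` and ``traces_b`` are (n_images, n_bins) arrays over the
    *same* image set (paired).  Latency is the start of the first rejected
    run of at least ``min_run`` bins."""
    a = np.asarray(traces_a, float)
    b = np.asarray(traces_b, float)
    if a.shape != b.shape:
        raise ValueError("paired trace arrays must have identical shape")
    if a.shape[0] < 3:
        raise InsufficientPairsError("paired tests need at least 3 images")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_rel(a, b, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    rejected = bh_fdr(p, q)
    runs = _runs(rejected)
    latency = None
    for s, l in runs:
        if l >= min_run:
            latency = float(s)
            break
    return SignificanceTrace(p, rejected, runs, latency, q, min_run)


def wilcoxon_check(values_a, values_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired image values.

    Uses the exact null distribution for n <= 25 non-zero differences
    without ties, the normal approximation otherwise.  Identical pairs
    (all-zero differences) are degenerate and return p = 1."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    return float(stats.wilcoxon(a, b, zero_method="wilcox",
                                method=method).pvalue)


def halfmax_latency(trace, baseline_ms=(0, 60)) -> float:
    """Time (ms) of the first half-max crossing of a trial-averaged trace.

    Baseline is the mean over ``baseline_ms``; the crossing is linearly
    interpolated between bins."""
    trace = np.asarray(trace, float)
    b0, b1 = int(baseline_ms[0]), int(baseline_ms[1])
    base = trace[b0:b1].mean()
    post = trace[b1:]
    peak = post.max()
    if peak <= base:
        return float("nan")
    half = base + 0.5 * (peak - base)
    idx = np.nonzero(post >= half)[0][0]
    if idx == 0:
        return float(b1)
    y0, y1 = post[idx - 1], post[idx]
    frac = (half - y0) / (y1 - y0) if y1 > y0 else 0.0
    return float(b1 + idx - 1 + frac)


def channel_difference_histogram(maps_by_channel: dict, scenes,
                                 key_a: str, key_b: str,
                                 key_by: str = "name"):
    """Mean map value over region A minus region B, per channel per image.

    ``maps_by_channel`` is channel -> {scene_id -> ResponseMap}.  Returns
    ``(per_channel, per_image)`` data frames; ``per_image`` holds the
    across-channel mean difference per image."""
    scenes = {s.scene_id: s for s in scenes}
    rows = []
    for ch, maps in maps_by_channel.items():
        for sid, rmap in maps.items():
            scene = scenes[sid]
            ra = scene.regions_by(key_a, by=key_by)
            rb = scene.regions_by(key_b, by=key_by)
            if not ra or not rb:
                continue
            X, Y = np.meshgrid(rmap.xs, rmap.ys)
            in_a = np.zeros(X.shape, bool)
            in_b = np.zeros(X.shape, bool)
            for r in ra:
                in_a |= r.shape.contains(X, Y)
            for r in rb:
                in_b |= r.shape.contains(X, Y)
            if not in_a.any() or not in_b.any():
                continue
            diff = (np.nanmean(rmap.values[in_a])
                    - np.nanmean(rmap.values[in_b]))
            rows.append({"scene_id": sid, "channel": ch,
                         "difference_hz": float(diff)})
    per_channel = pd.DataFrame(rows)
    if per_channel.empty:
        raise EmptyRegionError("no map samples either region")
    per_image = (per_channel.groupby("scene_id")["difference_hz"]
                 .mean().reset_index())
    return per_channel, per_image
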