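"""Receptive-field estimation and category tuning.

Probe responses are windowed, baseline-subtracted firing rates (mean rate
over 80-250 ms after onset minus the mean rate over the first 30 ms),
averaged across repetitions per grid position.  A 2D Gaussian
``offset + amplitude * exp(-dx^2/2sx^2 - dy^2/2sy^2)`` is fit to each
channel's response grid to derive the RF centroid and widths (1 sigma); the
population RF is the mean grid across channels.  Category selectivity uses
the bounded index ``(r1 - r2) / (r1 + r2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .scenes import PresentationProtocol
from .simulator import SpikeRecord

WINDOW_EVOKED = (80.0, 250.0)
WINDOW_BASELINE = (0.0, 30.0)


class DegenerateFitError(ValueError):
    """Raised when a response grid carries no fittable structure."""


class UndefinedIndexError(ZeroDivisionError):
    """Raised when a selectivity index has a zero denominator."""


@dataclass
class ResponseGrid:
    """Baseline-subtracted mean rates on a probe grid.

    ``values[iy, ix]`` corresponds to ``(ys[iy], xs[ix])``; both axes are
    ascending in degrees.  Positions never presented are NaN with
    ``missing`` set."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray
    n_reps: np.ndarray
    window_evoked: tuple = WINDOW_EVOKED
    window_baseline: tuple = WINDOW_BASELINE

    @property
    def missing(self):
        return self.n_reps == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ys, name="y_deg"),
                            columns=pd.Index(self.xs, name="x_deg"))


@dataclass
class RFFit:
    """2D Gaussian receptive-field fit."""

    centroid_deg: tuple
    sigma_deg: tuple
    amplitude_hz: float
    offset_hz: float
    goodness: float


def windowed_rates(record: SpikeRecord, onsets, channel: int,
                   window_evoked=WINDOW_EVOKED, window_baseline=WINDOW_BASELINE):
    """Per-presentation evoked-minus-baseline rate (Hz)."""
    ev = record.counts_in_window(channel, onsets, window_evoked)
    bl = record.counts_in_window(channel, onsets, window_baseline)
    dur_ev = (window_evoked[1] - window_evoked[0]) / 1000.0
    dur_bl = (window_baseline[1] - window_baseline[0]) / 1000.0
    return ev / dur_ev - bl / dur_bl


def probe_response_grid(record: SpikeRecord, protocol: PresentationProtocol,
                        channel: int, window_evoked=WINDOW_EVOKED,
                        window_baseline=WINDOW_BASELINE,
                        baseline: str = "pooled") -> ResponseGrid:
    """Average the evoked response over repetitions at each grid position.

    With ``baseline="pooled"`` (default) the channel's baseline-window rate is
    pooled across all presentations before subtraction — the spontaneous rate
    is stationary, so this estimates the same quantity as the per-presentation
    pairing (``baseline="paired"``) with far less variance from the short
    30 ms window."""
    ev = protocol.events
    onsets = ev["onset_ms"].to_numpy(float)
    if baseline == "pooled":
        dur_ev = (window_evoked[1] - window_evoked[0]) / 1000.0
        dur_bl = (window_baseline[1] - window_baseline[0]) / 1000.0
        base = record.counts_in_window(channel, onsets, window_baseline).mean() / dur_bl
        resp = record.counts_in_window(channel, onsets, window_evoked) / dur_ev - base
    elif baseline == "paired":
        resp = windowed_rates(record, onsets, channel,
                              window_evoked, window_baseline)
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    df = pd.DataFrame({"gx": ev["grid_x"], "gy": ev["grid_y"], "resp": resp})
    agg = df.groupby(["gy", "gx"])["resp"].agg(["mean", "count"])
    xs = np.asarray(protocol.grid_x, float)
    ys = np.asarray(protocol.grid_y, float)
    values = np.full((ys.size, xs.size), np.nan)
    n_reps = np.zeros((ys.size, xs.size), int)
    xi = {round(x, 9): i for i, x in enumerate(xs)}
    yi = {round(y, 9): i for i, y in enumerate(ys)}
    for (gy, gx), row in agg.iterrows():
        values[yi[round(gy, 9)], xi[round(gx, 9)]] = row["mean"]
        n_reps[yi[round(gy, 9)], xi[round(gx, 9)]] = int(row["count"])
    return ResponseGrid(xs, ys, values, n_reps, window_evoked, window_baseline)


def _gauss2d(p, X, Y):
    if len(p) == 6:
        x0, y0, sx, sy, amp, off = p
    else:
        x0, y0, sx, amp, off = p
        sy = sx
    return off + amp * np.exp(-((X - x0) ** 2) / (2 * sx ** 2)
                              - ((Y - y0) ** 2) / (2 * sy ** 2))


def fit_rf_gaussian(grid: ResponseGrid, independent_sigma: bool = True) -> RFFit:
    """Bounded nonlinear least-squares fit of a 2D Gaussian to the grid.

    Missing positions are excluded from the loss.  Multi-start initialisation
    (grid argmax and positive-mass centroid) makes the noiseless round trip
    exact to optimizer precision.  A flat grid raises
    :class:`DegenerateFitError`.
    """
    X, Y = np.meshgrid(grid.xs, grid.ys)
    valid = np.isfinite(grid.values)
    if valid.sum() < 6:
        raise DegenerateFitError("fewer than 6 valid grid points")
    v = grid.values[valid]
    x, y = X[valid], Y[valid]
    vrange = float(v.max() - v.min())
    if vrange <= 0:
        raise DegenerateFitError("flat response grid has no fittable structure")
    sp = grid.spacing if hasattr(grid, "spacing") else float(np.diff(grid.xs).mean())
    span = max(grid.xs.max() - grid.xs.min(), grid.ys.max() - grid.ys.min())
    imax = np.argmax(v)
    w = np.clip(v - v.min(), 0, None)
    cx, cy = np.average(x, weights=w), np.average(y, weights=w)
    mx = max(sp, np.sqrt(np.average((x - cx) ** 2, weights=w)))
    my = max(sp, np.sqrt(np.average((y - cy) ** 2, weights=w)))
    if independent_sigma:
        starts = [(x[imax], y[imax], sp, sp, vrange, v.min()),
                  (cx, cy, mx, my, vrange, v.min())]
        lb = [grid.xs.min() - sp, grid.ys.min() - sp, 0.05, 0.05, 1e-9,
              v.min() - 2 * vrange]
        ub = [grid.xs.max() + sp, grid.ys.max() + sp, 2 * span, 2 * span,
              10 * vrange, v.max() + 2 * vrange]
    else:
        starts = [(x[imax], y[imax], sp, vrange, v.min()),
                  (cx, cy, np.sqrt(mx * my), vrange, v.min())]
        lb = [grid.xs.min() - sp, grid.ys.min() - sp, 0.05, 1e-9,
              v.min() - 2 * vrange]
        ub = [grid.xs.max() + sp, grid.ys.max() + sp, 2 * span,
              10 * vrange, v.max() + 2 * vrange]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        res = optimize.least_squares(
            lambda p: _gauss2d(p, x, y) - v, p0, bounds=(lb, ub),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    if independent_sigma:
        x0, y0, sx, sy, amp, off = best.x
    else:
        x0, y0, sx, amp, off = best.x
        sy = sx
    ss_res = 2 * best.cost
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    goodness = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RFFit((float(x0), float(y0)), (float(sx), float(sy)),
                 float(amp), float(off), float(goodness))


def population_rf(grids) -> ResponseGrid:
    """Pointwise mean of per-channel response grids (the population RF)."""
    grids = list(grids)
    xs, ys = grids[0].xs, grids[0].ys
    for g in grids[1:]:
        if not (np.array_equal(g.xs, xs) and np.array_equal(g.ys, ys)):
            raise ValueError("response grids are on mismatched axes")
    stack = np.stack([g.values for g in grids])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    n_reps = np.sum([g.n_reps for g in grids], axis=0)
    return ResponseGrid(xs, ys, mean, n_reps,
                        grids[0].window_evoked, grids[0].window_baseline)


def selectivity_index(r1: float, r2: float) -> float:
    """Bounded category contrast ``(r1 - r2) / (r1 + r2)``."""
    denom = r1 + r2
    if denom == 0:
        raise UndefinedIndexError("selectivity index undefined for r1 + r2 = 0")
    return (r1 - r2) / denom


@dataclass
class CategoryTuning:
    """Windowed mean responses (channel x category) plus population PSTHs."""

    means: pd.DataFrame
    psths: dict


def category_tuning(record: SpikeRecord, protocol: PresentationProtocol,
                    category_of_scene: dict, window_evoked=WINDOW_EVOKED,
                    window_baseline=WINDOW_BASELINE, epoch_ms: int = 300,
                    smooth_sigma_ms: float = 5.0) -> CategoryTuning:
    """Per-channel baseline-subtracted mean response per stimulus category,
    plus a smoothed population PSTH per category."""
    ev = protocol.events
    cats = ev["scene_id"].map(category_of_scene)
    onsets = ev["onset_ms"].to_numpy(float)
    channels = record.channels
    rows = {}
    psths = {}
    for cat in sorted(set(category_of_scene.values())):
        sel = (cats == cat).to_numpy()
        if not sel.any():
            continue
        per_ch = []
        trace = np.zeros(epoch_ms)
        for ch in channels:
            per_ch.append(float(np.mean(windowed_rates(
                record, onsets[sel], ch, window_evoked, window_baseline))))
            for onset in onsets[sel]:
                trace += record.binned_counts(ch, onset, epoch_ms)
        rows[cat] = per_ch
        trace = trace / (sel.sum() * len(channels)) * 1000.0
        psths[cat] = ndimage.gaussian_filter1d(trace, smooth_sigma_ms,
                                               truncate=2.0, mode="nearest")
    means = pd.DataFrame(rows, index=pd.Index(channels, name="channel"))
    return CategoryTuning(means, psths)


def category_selectivity(means: pd.DataFrame, cat1: str, cat2: str,
                         exclude_negative: bool = True) -> dict:
    """Mean/SD of per-channel selectivity indices between two categories.

    Channels with a negative response to either category are excluded from
    the index (their count is reported)."""
    r1 = means[cat1].to_numpy(float)
    r2 = means[cat2].to_numpy(float)
    keep = np.ones(r1.size, bool)
    if exclude_negative:
        keep = (r1 >= 0) & (r2 >= 0)
    idx = np.array([selectivity_index(a, b) for a, b in zip(r1[keep], r2[keep])])
    return {"indices": idx, "mean": float(idx.mean()) if idx.size else np.nan,
            "std": float(idx.std(ddof=1)) if idx.size > 1 else np.nan,
            "n_excluded": int((~keep).sum())}


def responsive_channels(record: SpikeRecord, protocol: PresentationProtocol,
                        z_threshold: float = 2.0) -> list:
    """Visually responsive channels: evoked rate above baseline rate with
    z >= threshold over all probe presentations."""
    onsets = protocol.events["onset_ms"].to_numpy(float)
    out = []
    for ch in record.channels:
        resp = windowed_rates(record, onsets, ch)
        z = resp.mean() / (resp.std(ddof=1) / np.sqrt(resp.size) + 1e-12)
        if z >= z_threshold:
            out.append(ch)
    return out
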