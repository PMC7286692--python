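"""Scene response maps in image coordinates.

A scene presented with its centre at grid position ``g`` puts image
coordinate ``c = r - g`` over the receptive-field centre ``r``.  Averaging
the windowed firing rate over repetitions of each grid position therefore
yields a map indexed by *image* coordinate: which part of the scene drove
the cell when it lay over the RF.  This sign convention (no mirroring) is
the single most error-prone step of the analysis and is pinned down by the
oracle map constructor below, which pushes the noise-free drive-rate model
through the identical registration code path.

Dense renderings interpolate bilinearly between grid nodes (no
extrapolation), and display scaling clips at the 0.5 / 99.5 percentiles of
the dense map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .scenes import PresentationProtocol, SceneSpec
from .simulator import ArrayModel, FaceCellModel, SpikeRecord, drive_rate

WINDOW_MAP = (100.0, 250.0)


@dataclass
class ResponseMap:
    """Mean windowed firing rate (Hz) indexed by image coordinate.

    ``values[iy, ix]`` corresponds to image coordinate ``(ys[iy], xs[ix])``
    (degrees relative to the image centre, both axes ascending)."""

    scene_id: str
    channel: object           # channel index or "population"
    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray
    window_ms: tuple = WINDOW_MAP

    def argmax_coord(self):
        iy, ix = np.unravel_index(np.nanargmax(self.values), self.values.shape)
        return (float(self.xs[ix]), float(self.ys[iy]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ys, name="y_deg"),
                            columns=pd.Index(self.xs, name="x_deg"))


@dataclass
class DenseMap:
    """Bilinearly interpolated rendering of a ResponseMap."""

    scene_id: str
    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray


def image_coordinate(rf_center, grid_x, grid_y):
    """Image coordinate over the RF centre for image-centre position (g)."""
    return (np.asarray(rf_center[0], float) - np.asarray(grid_x, float),
            np.asarray(rf_center[1], float) - np.asarray(grid_y, float))


def _image_axes(rf_center, protocol: PresentationProtocol):
    cx = np.sort(rf_center[0] - np.asarray(protocol.grid_x, float))
    cy = np.sort(rf_center[1] - np.asarray(protocol.grid_y, float))
    return cx, cy


def build_scene_response_map(record: SpikeRecord, protocol: PresentationProtocol,
                             scene_id: str, channel, rf_center,
                             window_ms=WINDOW_MAP) -> ResponseMap:
    """Average windowed rates over repetitions and register them to image
    coordinates ``c = rf_center - g``.

    ``channel`` may be a channel index, a list of channels, or "population"
    (all channels pooled)."""
    ev = protocol.events
    sel = ev["scene_id"] == scene_id
    if not sel.any():
        raise KeyError(f"scene {scene_id!r} absent from protocol")
    ev = ev[sel]
    onsets = ev["onset_ms"].to_numpy(float)
    dur_s = (window_ms[1] - window_ms[0]) / 1000.0
    if channel == "population":
        chans = record.channels
    elif np.isscalar(channel):
        chans = [channel]
    else:
        chans = list(channel)
    rates = np.zeros(len(ev))
    for ch in chans:
        rates += record.counts_in_window(ch, onsets, window_ms) / dur_s
    rates /= len(chans)
    cx, cy = image_coordinate(rf_center, ev["grid_x"].to_numpy(float),
                              ev["grid_y"].to_numpy(float))
    axis_x, axis_y = _image_axes(rf_center, protocol)
    df = pd.DataFrame({"cx": np.round(cx, 9), "cy": np.round(cy, 9), "r": rates})
    agg = df.groupby(["cy", "cx"])["r"].mean()
    values = np.full((axis_y.size, axis_x.size), np.nan)
    xi = {round(v, 9): i for i, v in enumerate(axis_x)}
    yi = {round(v, 9): i for i, v in enumerate(axis_y)}
    for (y, x), r in agg.items():
        values[yi[y], xi[x]] = r
    label = "population" if channel == "population" else channel
    return ResponseMap(scene_id, label, axis_x, axis_y, values, tuple(window_ms))


def oracle_scene_response_map(model, protocol: PresentationProtocol,
                              scene: SceneSpec, rf_center,
                              window_ms=WINDOW_MAP) -> ResponseMap:
    """Noise-free reference map: the drive-rate model averaged over the
    analysis window, pushed through the same registration as the spike maps.

    ``model`` is a :class:`FaceCellModel` or an :class:`ArrayModel` (channel
    mean)."""
    cells = model.channels if isinstance(model, ArrayModel) else [model]
    t = np.arange(window_ms[0], window_ms[1]) + 0.5
    axis_x, axis_y = _image_axes(rf_center, protocol)
    values = np.zeros((axis_y.size, axis_x.size))
    for gx in protocol.grid_x:
        for gy in protocol.grid_y:
            cx, cy = image_coordinate(rf_center, gx, gy)
            ix = int(np.argmin(np.abs(axis_x - cx)))
            iy = int(np.argmin(np.abs(axis_y - cy)))
            rate = np.mean([drive_rate(c, scene, (gx, gy), t).mean()
                            for c in cells])
            values[iy, ix] = rate
    return ResponseMap(scene.scene_id, "oracle", axis_x, axis_y, values,
                       tuple(window_ms))


def interpolate_map(rmap: ResponseMap, px_per_deg: float) -> DenseMap:
    """Bilinear interpolation between grid nodes; node values preserved,
    no extrapolation beyond the outer nodes."""
    nx = int(round((rmap.xs.max() - rmap.xs.min()) * px_per_deg)) + 1
    ny = int(round((rmap.ys.max() - rmap.ys.min()) * px_per_deg)) + 1
    dense_x = np.linspace(rmap.xs.min(), rmap.xs.max(), nx)
    dense_y = np.linspace(rmap.ys.min(), rmap.ys.max(), ny)
    interp = RegularGridInterpolator((rmap.ys, rmap.xs), rmap.values,
                                     method="linear", bounds_error=True)
    YY, XX = np.meshgrid(dense_y, dense_x, indexing="ij")
    vals = interp(np.column_stack([YY.ravel(), XX.ravel()])).reshape(ny, nx)
    return DenseMap(rmap.scene_id, dense_x, dense_y, vals)


def scale_map(values, lo_pct: float = 0.5, hi_pct: float = 99.5) -> np.ndarray:
    """Affine rescale to [0, 1], clipping at per-image percentiles.

    A constant map comes back as a single mid-scale level."""
    v = values.values if isinstance(values, (ResponseMap, DenseMap)) else values
    v = np.asarray(v, float)
    finite = v[np.isfinite(v)]
    lo, hi = np.percentile(finite, [lo_pct, hi_pct])
    if hi <= lo:
        return np.full(v.shape, 0.5)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def temporal_maps(record: SpikeRecord, protocol: PresentationProtocol,
                  scene_id: str, channel, rf_center, bin_ms: float = 40.0,
                  t_range=(50.0, 250.0)):
    """One ResponseMap per half-open time bin [t, t + bin_ms)."""
    starts = np.arange(t_range[0], t_range[1], bin_ms)
    return [build_scene_response_map(record, protocol, scene_id, channel,
                                     rf_center, (t0, min(t0 + bin_ms, t_range[1])))
            for t0 in starts]


def population_map(maps) -> ResponseMap:
    """Pointwise mean over per-channel maps of the same scene and grid."""
    maps = list(maps)
    first = maps[0]
    for m in maps[1:]:
        if not (np.array_equal(m.xs, first.xs) and np.array_equal(m.ys, first.ys)):
            raise ValueError("response maps are on mismatched grids")
    stack = np.stack([m.values for m in maps])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return ResponseMap(first.scene_id, "population", first.xs, first.ys,
                       mean, first.window_ms)


@dataclass
class OrientationComposite:
    """Best body orientation per image grid point, with a baseline mask."""

    xs: np.ndarray
    ys: np.ndarray
    best_orientation_deg: np.ndarray
    masked: np.ndarray
    orientations: tuple

    def to_frame(self) -> pd.DataFrame:
        out = np.where(self.masked, np.nan, self.best_orientation_deg)
        return pd.DataFrame(out, index=pd.Index(self.ys, name="y_deg"),
                            columns=pd.Index(self.xs, name="x_deg"))


def composite_orientation_map(maps: dict, baseline_hz: float) -> OrientationComposite:
    """At each grid point, the orientation with the maximal response; points
    where every orientation responds at or below baseline are masked.

    ``maps`` is orientation (deg) -> ResponseMap on a common grid.  Ties go
    to the lowest orientation."""
    orients = tuple(sorted(maps))
    first = maps[orients[0]]
    for th in orients[1:]:
        m = maps[th]
        if not (np.array_equal(m.xs, first.xs) and np.array_equal(m.ys, first.ys)):
            raise ValueError("orientation maps are on mismatched grids")
    stack = np.stack([maps[th].values for th in orients])
    best = np.nanargmax(stack, axis=0)
    best_deg = np.asarray(orients, float)[best]
    with np.errstate(invalid="ignore"):
        masked = np.nanmax(stack, axis=0) <= baseline_hz
    return OrientationComposite(first.xs, first.ys, best_deg, masked, orients)
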