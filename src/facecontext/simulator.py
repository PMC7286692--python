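"""Inhomogeneous-Poisson spike simulation from a parametric face-cell model.

Each simulated channel is a face cell with a small 2D Gaussian receptive
field (RF) near fixation and a set of additive drives:

* ``eyes`` — early response to eye regions (default latency 70 ms),
* ``face`` — response to an intact face over the RF (default 95 ms),
* ``context_implied_face`` — a weaker, slower (default 130 ms) response to
  the point where a body implies a face ought to be,
* ``context_feet`` — a still weaker response when the feet of a body land in
  the RF.

Rates follow ``baseline + sum_d gain_d * G_d * k(t - latency_d)`` where
``G_d`` is the Gaussian RF evaluated at the drive location translated by the
grid position, and ``k`` is a unit-peak alpha-like kernel (10 ms rise and a
sustained 150 ms decay by default, so that responses span the 100-250 /
150-300 ms analysis windows the way real face-patch responses do).  Two qualitative rules of contextual facilitation are
built in: a *ceiling rule* (the context drive is suppressed when an intact
face already covers the implied-face point) and *inversion attenuation*
(sustained for ambiguous face stand-ins such as noise patches, transient —
confined to the kernel rise — for intact faces).

Spikes are drawn from the resulting rate as an inhomogeneous Poisson process
(1 ms bins, uniform jitter within the bin) on top of a shared homogeneous
baseline; no refractoriness is modelled, since every downstream statistic is
a windowed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .scenes import PresentationProtocol, SceneSpec

DRIVE_KINDS = ("eyes", "face", "context_implied_face", "context_feet")

DEFAULT_GAINS = {"eyes": 25.0, "face": 40.0,
                 "context_implied_face": 16.0, "context_feet": 8.0}
DEFAULT_LATENCIES = {"eyes": 70.0, "face": 95.0,
                     "context_implied_face": 130.0, "context_feet": 130.0}


def alpha_kernel(t, rise_ms: float = 10.0, decay_ms: float = 40.0):
    """Difference-of-exponentials kernel normalised to peak 1 at t > 0."""
    t = np.asarray(t, float)
    t_peak = rise_ms * decay_ms / (decay_ms - rise_ms) * np.log(decay_ms / rise_ms)
    norm = np.exp(-t_peak / decay_ms) - np.exp(-t_peak / rise_ms)
    tc = np.clip(t, 0.0, None)
    k = (np.exp(-tc / decay_ms) - np.exp(-tc / rise_ms)) / norm
    return np.where(t < 0, 0.0, k)


@dataclass(frozen=True)
class FaceCellModel:
    """Parametric tuning of one simulated recording site."""

    rf_center_deg: tuple = (1.0, -0.5)
    rf_sigma_deg: float = 1.0          # 1 sigma; activating regions 1-3 deg wide
    baseline_hz: float = 5.0
    gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    latencies_ms: dict = field(default_factory=lambda: dict(DEFAULT_LATENCIES))
    rise_ms: float = 10.0
    decay_ms: float = 150.0
    inversion_attenuation: float = 0.5
    ambiguous_face_strength: float = 0.3   # noise patches / outlines vs intact faces
    ceiling_rule: bool = True
    latency_offset_ms: float = 0.0         # area-level shift (PL earlier than ML)

    def __post_init__(self):
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("gains must be non-negative")
        if any(l < 0 for l in self.latencies_ms.values()):
            raise ValueError("latencies must be non-negative")
        if self.baseline_hz < 0:
            raise ValueError("baseline must be non-negative")


@dataclass(frozen=True)
class _Drive:
    kind: str
    loc: tuple
    strength: float = 1.0
    sustained_attenuation: float = 1.0
    transient_attenuation: float = 1.0


def scene_drives(cell: FaceCellModel, scene: SceneSpec):
    """The additive drives a scene exerts on a cell (before RF weighting)."""
    drives = []
    inv = cell.inversion_attenuation
    faces = [r for r in scene.regions if r.label == "face"]
    for r in scene.regions:
        if r.label == "face":
            drives.append(_Drive("face", r.center,
                                 transient_attenuation=inv if r.inverted else 1.0))
        elif r.label == "eyes":
            drives.append(_Drive("eyes", r.center))
        elif r.label in ("noise_patch", "outline"):
            # ambiguous face stand-ins: weak face-like drive, sustained
            # attenuation when inverted
            drives.append(_Drive("face", r.center,
                                 strength=cell.ambiguous_face_strength,
                                 sustained_attenuation=inv if r.inverted else 1.0))
        elif r.label == "body":
            anchor = r.implied_face
            covered = any(f.shape.contains(anchor[0], anchor[1]) for f in faces)
            if not (cell.ceiling_rule and covered):
                drives.append(_Drive("context_implied_face", tuple(anchor),
                                     sustained_attenuation=inv if r.inverted else 1.0))
            if r.implied_feet is not None:
                drives.append(_Drive("context_feet", tuple(r.implied_feet),
                                     sustained_attenuation=inv if r.inverted else 1.0))
    return drives


def drive_rate(cell: FaceCellModel, scene: SceneSpec, grid_pos, t):
    """Instantaneous firing rate (Hz) at time ``t`` (ms) after stimulus onset
    for a scene presented with its centre at ``grid_pos``."""
    t = np.asarray(t, float)
    rate = np.full(t.shape, cell.baseline_hz)
    two_s2 = 2.0 * cell.rf_sigma_deg ** 2
    rx, ry = cell.rf_center_deg
    for d in scene_drives(cell, scene):
        dx = d.loc[0] + grid_pos[0] - rx
        dy = d.loc[1] + grid_pos[1] - ry
        g = np.exp(-(dx * dx + dy * dy) / two_s2)
        if g < 1e-8:
            continue
        lat = cell.latencies_ms[d.kind] + cell.latency_offset_ms
        k = alpha_kernel(t - lat, cell.rise_ms, cell.decay_ms)
        k = k * d.sustained_attenuation
        if d.transient_attenuation != 1.0:
            k = np.where(t - lat < 2.0 * cell.rise_ms,
                         k * d.transient_attenuation, k)
        rate = rate + cell.gains[d.kind] * d.strength * g * k
    return rate


@dataclass
class ArrayModel:
    """A multi-electrode array: channels with jittered RF centres."""

    channels: list
    area_label: str = "ML"
    area_latency_offset_ms: float = 0.0

    def __post_init__(self):
        if not self.channels:
            raise ValueError("array needs at least one channel")

    @property
    def n_channels(self):
        return len(self.channels)

    @property
    def rf_center(self):
        centers = np.array([c.rf_center_deg for c in self.channels])
        return tuple(centers.mean(axis=0))


def make_array(n_channels: int = 8, center=(1.0, -0.5), jitter_deg: float = 0.15,
               rf_sigma_deg: float = 1.0, seed: int = 0, area_label: str = "ML",
               area_latency_offset_ms: float = 0.0, **cell_kwargs) -> ArrayModel:
    """Channels share tuning; RF centres are jittered around ``center``.

    ``area_latency_offset_ms`` shifts every latency (PL earlier than ML, e.g.
    -10 ms for a PL array)."""
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_channels):
        jit = rng.normal(0.0, jitter_deg, 2)
        cells.append(FaceCellModel(
            rf_center_deg=(center[0] + jit[0], center[1] + jit[1]),
            rf_sigma_deg=rf_sigma_deg,
            latency_offset_ms=area_latency_offset_ms, **cell_kwargs))
    return ArrayModel(cells, area_label, area_latency_offset_ms)


@dataclass
class SpikeRecord:
    """Per-channel sorted spike-event times (ms) for one session."""

    spike_times: dict
    duration_ms: float
    protocol: PresentationProtocol | None = None

    @property
    def channels(self):
        return sorted(self.spike_times)

    def counts_in_window(self, channel: int, onsets, window) -> np.ndarray:
        """Spike counts in ``[onset+window[0], onset+window[1])`` per onset."""
        times = self.spike_times[channel]
        onsets = np.asarray(onsets, float)
        lo = np.searchsorted(times, onsets + window[0])
        hi = np.searchsorted(times, onsets + window[1])
        return hi - lo

    def binned_counts(self, channel: int, onset: float, epoch_ms: int) -> np.ndarray:
        """1 ms-binned counts for a single presentation epoch."""
        times = self.spike_times[channel]
        lo = np.searchsorted(times, onset)
        hi = np.searchsorted(times, onset + epoch_ms)
        rel = times[lo:hi] - onset
        return np.bincount(rel.astype(int), minlength=epoch_ms)[:epoch_ms]

    def to_frame(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"channel": ch, "t_ms": self.spike_times[ch]})
                 for ch in self.channels]
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.attrs["duration_ms"] = self.duration_ms
            for ch, t in self.spike_times.items():
                fh.create_dataset(f"channel_{ch:03d}", data=t)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, duration_ms: float | None = None):
        spikes = {int(ch): np.sort(g["t_ms"].to_numpy(float))
                  for ch, g in frame.groupby("channel")}
        if duration_ms is None:
            duration_ms = float(frame["t_ms"].max()) + 1.0
        return cls(spikes, duration_ms)


def simulate_session(array: ArrayModel, protocol: PresentationProtocol,
                     scenes: Iterable[SceneSpec], seed: int,
                     epoch_ms: int = 350) -> SpikeRecord:
    """Draw a full session of spikes for every channel of the array.

    Evoked activity is sampled per presentation epoch from the drive-rate
    model; a homogeneous baseline runs for the whole session, so overlapping
    epochs superpose additively above a single shared baseline.
    """
    by_id = {s.scene_id: s for s in scenes}
    ev = protocol.events
    missing = set(ev["scene_id"]) - set(by_id)
    if missing:
        raise KeyError(f"protocol references unknown scenes: {sorted(missing)}")
    onsets = ev["onset_ms"].to_numpy(float)
    keys = list(zip(ev["scene_id"], ev["grid_x"], ev["grid_y"]))
    uniq = sorted(set(keys))
    key_index = {k: i for i, k in enumerate(uniq)}
    ev_key = np.array([key_index[k] for k in keys])
    t = np.arange(epoch_ms) + 0.5
    duration = float(onsets.max() + epoch_ms + 500.0)
    children = np.random.SeedSequence(seed).spawn(array.n_channels)
    spike_times = {}
    for ch, (cell, ss) in enumerate(zip(array.channels, children)):
        rng = np.random.default_rng(ss)
        evoked = np.empty((len(uniq), epoch_ms))
        for i, (sid, gx, gy) in enumerate(uniq):
            r = drive_rate(cell, by_id[sid], (gx, gy), t) - cell.baseline_hz
            evoked[i] = np.clip(r, 0.0, None)
        lam = evoked[ev_key] / 1000.0
        counts = rng.poisson(lam)
        ei, bi = np.nonzero(counts)
        reps = counts[ei, bi]
        ei = np.repeat(ei, reps)
        bi = np.repeat(bi, reps)
        times = onsets[ei] + bi + rng.random(ei.size)
        n_base = rng.poisson(cell.baseline_hz * duration / 1000.0)
        base = rng.random(n_base) * duration
        spike_times[ch] = np.sort(np.concatenate([times, base]))
    return SpikeRecord(spike_times, duration, protocol)


def simulate_probe_session(array: ArrayModel, grid_shape=9, spacing_deg: float = 1.0,
                           grid_center_deg=(0.0, 0.0), reps: int = 10, seed: int = 0,
                           probe: SceneSpec | None = None, epoch_ms: int = 350):
    """Receptive-field mapping session: a small face probe flashed over a
    grid of positions.  Returns ``(record, protocol, scenes)``."""
    from .scenes import make_probe_scene, make_protocol

    probe = probe or make_probe_scene()
    protocol = make_protocol(grid_shape, spacing_deg, grid_center_deg,
                             [probe], reps, seed)
    record = simulate_session(array, protocol, [probe], seed + 1, epoch_ms)
    return record, protocol, {probe.scene_id: probe}
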