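"""Run configuration: serializable parameters for the end-to-end pipeline.

A run is reproducible from (config, seed) alone.  The two monkey profiles
mirror the two presentation regimes: a 17 x 17 grid at 1 deg spacing with a
100-250 ms analysis window, or a 9 x 9 grid at 2 deg spacing with a
150-300 ms window.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .scenes import ARCHETYPES

PROFILES = {
    "monkey1": {"grid_shape": 17, "spacing_deg": 1.0, "window_ms": (100.0, 250.0)},
    "monkey2": {"grid_shape": 9, "spacing_deg": 2.0, "window_ms": (150.0, 300.0)},
}


@dataclass
class RunConfig:
    seed: int = 0
    profile: str = "monkey2"
    outdir: str = "runs/default"
    # simulated array
    n_channels: int = 4
    rf_center: tuple = (1.0, -0.5)
    rf_sigma_deg: float = 1.0
    baseline_hz: float = 5.0
    context_gain_fraction: float = 0.4   # context gain relative to face gain
    # presentation
    reps: int = 5
    n_exemplars: int = 3
    archetypes: tuple = ("intact", "occluded", "body_orientations")
    px_per_deg: float = 4.0
    # statistics
    q: float = 0.05
    smooth_window_ms: float = 20.0
    smooth_sigma_ms: float = 5.0
    min_run_bins: int = 5
    # rsa
    rsa_n_per_category: int = 20
    rsa_n_features: int = 64
    rsa_face_body_shared: float = 0.8
    rsa_n_permutations: int = 200
    allow_nonstandard_reps: bool = False

    @property
    def grid_shape(self):
        return PROFILES[self.profile]["grid_shape"]

    @property
    def spacing_deg(self):
        return PROFILES[self.profile]["spacing_deg"]

    @property
    def window_ms(self):
        return PROFILES[self.profile]["window_ms"]

    def to_json(self, path=None):
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def validate_config(config: RunConfig) -> list:
    """Itemized validation errors; an empty list means the config is valid."""
    errors = []
    if config.profile not in PROFILES:
        errors.append(f"unknown profile {config.profile!r}")
    if not (5 <= config.reps <= 10) and not config.allow_nonstandard_reps:
        errors.append(f"reps={config.reps} outside the standard 5-10 range "
                      "(set allow_nonstandard_reps to override)")
    if not (0.0 < config.q < 1.0):
        errors.append(f"q={config.q} must lie in (0, 1)")
    for a in config.archetypes:
        if a not in ARCHETYPES:
            errors.append(f"unknown archetype {a!r}")
    if config.n_channels < 1:
        errors.append("n_channels must be >= 1")
    if config.n_exemplars < 1:
        errors.append("n_exemplars must be >= 1")
    if config.rf_sigma_deg <= 0:
        errors.append("rf_sigma_deg must be positive")
    if config.min_run_bins < 1:
        errors.append("min_run_bins must be >= 1")
    return errors
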