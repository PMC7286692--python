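"""Parametric labeled scenes and presentation protocols.

The stimuli are not photographs but parametric shape layouts that preserve the
*relational* structure the analysis consumes: a face-shaped region that may be
intact, masked, occluded, swapped for an object, or replaced by noise; a body
below (or above, when inverted) carrying an "implied face" anchor — the point
where a face ought to be given the body's position and orientation; and
control regions of matched size placed elsewhere on the canvas.

Seven image-set archetypes are available (`make_scene_set`):

``intact``                unaltered scenes: face (+eyes) above a body
``masked``                face covered by a mask/bag over the face footprint
``occluded``              face hidden behind an occluding object
``face_swapped``          the same non-face object twice, once above a body
``face_variants_x_body``  4 face variants x {above body, no body} matched pairs
``body_orientations``     one body per exemplar at 8 orientations (45 deg steps)
``upright_inverted``      {intact, noise} x {upright, inverted} matched pairs

Scenes live on a 16 x 16 deg canvas.  Region positions are snapped to a 2 deg
lattice so that presentation grids (1 or 2 deg spacing, centered on the
population receptive field) sample region centres exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Ellipse, rasterize, raster_coords, rotate_point, shape_from_dict

REGION_LABELS = (
    "face", "eyes", "body", "occluder", "mask_cover", "object",
    "noise_patch", "outline", "background_control",
)

ARCHETYPES = (
    "intact", "masked", "occluded", "face_swapped",
    "face_variants_x_body", "body_orientations", "upright_inverted",
)

CANVAS_DEG = 16.0

# layout constants (degrees)
FACE_RX, FACE_RY = 0.8, 1.0
BODY_RX, BODY_RY = 1.1, 1.9
HEAD_OFFSET = 2.6    # body centre -> implied face, along the body axis
FEET_OFFSET = 2.4    # body centre -> feet, opposite direction


class UnknownArchetypeError(ValueError):
    """Raised for an image-set archetype that is not one of the seven."""


@dataclass(frozen=True)
class Region:
    """A labeled region of a scene.

    ``implied_face`` is required for bodies: the point where a face ought to
    be given the body's position and orientation.  ``inverted`` marks regions
    belonging to an inverted face-body configuration.  ``name`` disambiguates
    multiple regions sharing a label (e.g. the two objects of a face-swapped
    scene); it defaults to the label.
    """

    label: str
    shape: object
    orientation_deg: float = 0.0
    implied_face: tuple | None = None
    implied_feet: tuple | None = None
    inverted: bool = False
    name: str | None = None

    def __post_init__(self):
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if self.name is None:
            object.__setattr__(self, "name", self.label)

    @property
    def center(self):
        return self.shape.centroid

    def to_dict(self):
        return {
            "label": self.label,
            "shape": self.shape.to_dict(),
            "orientation_deg": self.orientation_deg,
            "implied_face": list(self.implied_face) if self.implied_face else None,
            "implied_feet": list(self.implied_feet) if self.implied_feet else None,
            "inverted": self.inverted,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            label=d["label"], shape=shape_from_dict(d["shape"]),
            orientation_deg=d.get("orientation_deg", 0.0),
            implied_face=tuple(d["implied_face"]) if d.get("implied_face") else None,
            implied_feet=tuple(d["implied_feet"]) if d.get("implied_feet") else None,
            inverted=d.get("inverted", False), name=d.get("name"),
        )


@dataclass(frozen=True)
class SceneSpec:
    """A labeled synthetic stimulus on a square canvas."""

    scene_id: str
    regions: tuple
    image_set: str
    canvas_deg: float = CANVAS_DEG
    pair_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        validate_scene(self)

    def regions_by(self, key, by="label"):
        attr = "name" if by == "name" else "label"
        return [r for r in self.regions if getattr(r, attr) == key]

    def to_dict(self):
        return {
            "scene_id": self.scene_id,
            "regions": [r.to_dict() for r in self.regions],
            "image_set": self.image_set,
            "canvas_deg": self.canvas_deg,
            "pair_id": self.pair_id,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            scene_id=d["scene_id"],
            regions=tuple(Region.from_dict(r) for r in d["regions"]),
            image_set=d["image_set"], canvas_deg=d.get("canvas_deg", CANVAS_DEG),
            pair_id=d.get("pair_id"), meta=d.get("meta", {}),
        )


def validate_scene(scene: SceneSpec) -> None:
    half = scene.canvas_deg / 2.0
    for r in scene.regions:
        x0, y0, x1, y1 = r.shape.bounds
        if x0 < -half - 1e-9 or y0 < -half - 1e-9 or x1 > half + 1e-9 or y1 > half + 1e-9:
            raise ValueError(
                f"region {r.name!r} of scene {scene.scene_id!r} exceeds the canvas")
        if r.label == "body":
            if r.implied_face is None or not np.all(np.isfinite(r.implied_face)):
                raise ValueError(
                    f"body region of scene {scene.scene_id!r} lacks an implied_face")
        if r.orientation_deg % 45 != 0:
            raise ValueError("orientation_deg must be a multiple of 45")


def save_scenes(path, scenes: Iterable[SceneSpec]) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in scenes], fh, indent=1)


def load_scenes(path):
    with open(path) as fh:
        return [SceneSpec.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# scene-set factories
# ---------------------------------------------------------------------------

def _lattice_candidates(ys):
    return [(float(x), float(y)) for x in (-4, -2, 0, 2, 4) for y in ys]


def _pick_position(rng, candidates, avoid=(), min_dist=3.9):
    ok = [c for c in candidates
          if all(np.hypot(c[0] - a[0], c[1] - a[1]) >= min_dist for a in avoid)]
    if not ok:
        raise ValueError("no admissible lattice position")
    return ok[rng.integers(len(ok))]


def _face_region(pos, **kw):
    return Region("face", Ellipse(pos, FACE_RX, FACE_RY), **kw)


def _eyes_region(pos):
    return Region("eyes", Ellipse((pos[0], pos[1] + 0.35), 0.55, 0.18))


def _body_region(face_pos, orientation_deg=0.0, inverted=False):
    """Body whose head-end points at ``face_pos`` for the given orientation."""
    axis = rotate_point((0.0, HEAD_OFFSET), orientation_deg)
    center = (face_pos[0] - axis[0], face_pos[1] - axis[1])
    feet = rotate_point((0.0, -FEET_OFFSET), orientation_deg)
    return Region(
        "body", Ellipse(center, BODY_RX, BODY_RY, rotation_deg=orientation_deg),
        orientation_deg=orientation_deg, implied_face=tuple(face_pos),
        implied_feet=(center[0] + feet[0], center[1] + feet[1]),
        inverted=inverted)


def _control_region(pos):
    return Region("background_control", Ellipse(pos, FACE_RX, FACE_RY))


def make_scene_set(archetype: str, n_exemplars: int, seed: int,
                   include_eyes: bool = True):
    """Generate ``n_exemplars`` worth of scenes for one image-set archetype.

    Exemplars differ in the (seeded) lattice position of the face/body group
    and of the control regions.  Matched pairs (face-variants with/without a
    body; upright/inverted configurations) share a ``pair_id`` and the same
    face-shaped footprint.
    """
    if archetype not in ARCHETYPES:
        raise UnknownArchetypeError(f"unknown image-set archetype {archetype!r}")
    if n_exemplars < 1:
        raise ValueError("n_exemplars must be >= 1")
    rng = np.random.default_rng(seed)
    scenes: list[SceneSpec] = []
    for i in range(n_exemplars):
        sid = f"{archetype}:{i:02d}"
        if archetype == "intact":
            pf = _pick_position(rng, _lattice_candidates((-2, 0, 2, 4)))
            pc = _pick_position(rng, _lattice_candidates((-4, -2, 0, 2, 4)), [pf])
            regions = [_face_region(pf), _body_region(pf), _control_region(pc)]
            if include_eyes:
                regions.insert(1, _eyes_region(pf))
            scenes.append(SceneSpec(sid, regions, archetype))
        elif archetype in ("masked", "occluded"):
            pf = _pick_position(rng, _lattice_candidates((-2, 0, 2, 4)))
            pc = _pick_position(rng, _lattice_candidates((-4, -2, 0, 2, 4)), [pf])
            if archetype == "masked":
                cover = Region("mask_cover", Ellipse(pf, FACE_RX, FACE_RY))
            else:
                cover = Region("occluder", Ellipse(pf, FACE_RX + 0.2, FACE_RY + 0.2))
            scenes.append(SceneSpec(
                sid, [cover, _body_region(pf), _control_region(pc)], archetype))
        elif archetype == "face_swapped":
            pf = _pick_position(rng, _lattice_candidates((-2, 0, 2, 4)))
            pc = _pick_position(rng, _lattice_candidates((-4, -2, 0, 2, 4)), [pf])
            atop = Region("object", Ellipse(pf, FACE_RX, 0.9), name="object_atop_body")
            ctrl = Region("object", Ellipse(pc, FACE_RX, 0.9), name="object_control")
            scenes.append(SceneSpec(sid, [atop, ctrl, _body_region(pf)], archetype))
        elif archetype == "face_variants_x_body":
            pf = _pick_position(rng, _lattice_candidates((-2, 0, 2)))
            pc = _pick_position(rng, _lattice_candidates((-4, -2, 0, 2, 4)), [pf])
            for variant in ("face", "noise_patch", "outline", "object"):
                for with_body in (True, False):
                    label = variant
                    footprint = Ellipse(pf, FACE_RX, FACE_RY)
                    var_region = Region(label, footprint, name="face_region")
                    regions = [var_region, _control_region(pc)]
                    if with_body:
                        regions.append(_body_region(pf))
                    suffix = "above_body" if with_body else "no_body"
                    scenes.append(SceneSpec(
                        f"{sid}:{variant}:{suffix}", regions, archetype,
                        pair_id=f"{sid}:{variant}",
                        meta={"variant": variant, "with_body": with_body,
                              "exemplar": i}))
        elif archetype == "body_orientations":
            for th in range(0, 360, 45):
                body = _body_region_at_center((0.0, 0.0), float(th))
                scenes.append(SceneSpec(
                    f"{sid}:{th:03d}", [body], archetype,
                    meta={"orientation_deg": th, "exemplar": i,
                          "with_head": False, "background": "white"}))
        elif archetype == "upright_inverted":
            pf = _pick_position(rng, _lattice_candidates((-2, 0)))
            pc = _pick_position(rng, _lattice_candidates((-4, -2, 0, 2, 4)), [pf])
            for variant in ("face", "noise_patch"):
                for inverted in (False, True):
                    footprint = Ellipse(pf, FACE_RX, FACE_RY)
                    var_region = Region(variant, footprint, name="face_region",
                                        inverted=inverted)
                    body = _body_region(pf, orientation_deg=180.0 if inverted else 0.0,
                                        inverted=inverted)
                    suffix = "inverted" if inverted else "upright"
                    scenes.append(SceneSpec(
                        f"{sid}:{variant}:{suffix}",
                        [var_region, body, _control_region(pc)], archetype,
                        pair_id=f"{sid}:{variant}",
                        meta={"variant": variant, "inverted": inverted,
                              "exemplar": i}))
    return scenes


def _body_region_at_center(center, orientation_deg):
    """Body centred at ``center``; implied face/feet rotate with the body."""
    head = rotate_point((0.0, HEAD_OFFSET), orientation_deg)
    feet = rotate_point((0.0, -FEET_OFFSET), orientation_deg)
    return Region(
        "body", Ellipse(center, BODY_RX, BODY_RY, rotation_deg=orientation_deg),
        orientation_deg=orientation_deg,
        implied_face=(center[0] + head[0], center[1] + head[1]),
        implied_feet=(center[0] + feet[0], center[1] + feet[1]))


def make_probe_scene(size_deg: float = 2.0, scene_id: str = "probe:face"):
    """A small (~2 x 2 deg) isolated face used for receptive-field mapping."""
    return SceneSpec(
        scene_id,
        [Region("face", Ellipse((0.0, 0.0), size_deg / 2.0, size_deg / 2.0))],
        "intact", meta={"probe": True, "background": "white"})


def make_category_probe_scenes(size_deg: float = 4.0):
    """Isolated face/hand/body/object images for category-tuning measurement.

    Each scene holds a single centred region on a white background, presented
    within the activating region (grid position 0,0).  Hands are modelled as
    objects (no intrinsic face drive); the isolated body carries its implied
    face above, outside the probed location.
    """
    r = size_deg / 2.0
    scenes = {
        "face": SceneSpec("cat:face",
                          [Region("face", Ellipse((0.0, 0.0), r * 0.8, r))],
                          "intact", meta={"category": "face", "background": "white"}),
        "hand": SceneSpec("cat:hand",
                          [Region("object", Ellipse((0.0, 0.0), r * 0.7, r * 0.9),
                                  name="hand")],
                          "intact", meta={"category": "hand", "background": "white"}),
        "body": SceneSpec("cat:body", [_body_region_at_center((0.0, 0.0), 0.0)],
                          "intact", meta={"category": "body", "background": "white"}),
        "object": SceneSpec("cat:object",
                            [Region("object", Ellipse((0.0, 0.0), r, r))],
                            "intact",
                            meta={"category": "object", "background": "white"}),
    }
    return scenes


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_LABEL_COLORS = {
    "face": (0.80, 0.62, 0.50),
    "eyes": (0.12, 0.09, 0.08),
    "body": (0.35, 0.40, 0.55),
    "occluder": (0.55, 0.38, 0.20),
    "mask_cover": (0.85, 0.82, 0.75),
    "object": (0.30, 0.55, 0.35),
}
_DRAW_ORDER = ("body", "object", "face", "mask_cover", "occluder",
               "noise_patch", "outline", "eyes")


def render_region_masks(scene: SceneSpec, px_per_deg: float, by: str = "label"):
    """Mutually registered boolean masks, keyed by region label (or name).

    With ``by='label'`` every label is present as a key; labels absent from
    the scene map to an all-false mask.
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    n = int(round(scene.canvas_deg * px_per_deg))
    keys = REGION_LABELS if by == "label" else [r.name for r in scene.regions]
    masks = {k: np.zeros((n, n), bool) for k in keys}
    for r in scene.regions:
        k = r.label if by == "label" else r.name
        masks[k] |= rasterize(r.shape, scene.canvas_deg, px_per_deg)
    return masks


def brown_noise(n: int, rng) -> np.ndarray:
    """An n x n random field with ~1/f^2 power spectrum, scaled to [0, 1]."""
    white = rng.standard_normal((n, n))
    f = np.hypot(np.fft.fftfreq(n)[:, None], np.fft.fftfreq(n)[None, :])
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / f[f > 0]
    img = np.fft.ifft2(np.fft.fft2(white) * amp).real
    lo, hi = img.min(), img.max()
    return (img - lo) / max(hi - lo, 1e-12)


def radial_power_slope(img: np.ndarray) -> float:
    """Log-log slope of the radially averaged power spectrum."""
    img = np.asarray(img, float)
    img = img - img.mean()
    P = np.abs(np.fft.fft2(img)) ** 2
    f = np.hypot(np.fft.fftfreq(img.shape[0])[:, None],
                 np.fft.fftfreq(img.shape[1])[None, :])
    sel = (f > 0) & (P > 0)
    lf, lp = np.log10(f[sel]), np.log10(P[sel])
    edges = np.linspace(lf.min(), lf.max() + 1e-9, 12)
    idx = np.digitize(lf, edges)
    xs = [lf[idx == b].mean() for b in range(1, 12) if (idx == b).sum() >= 4]
    ys = [lp[idx == b].mean() for b in range(1, 12) if (idx == b).sum() >= 4]
    return float(np.polyfit(xs, ys, 1)[0])


def render_image(scene: SceneSpec, px_per_deg: float, seed: int) -> np.ndarray:
    """RGB raster of the scene: brown-noise (or white) background with flat
    region patches; noise patches are filled with independent uniform values
    per colour channel."""
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(scene.canvas_deg * px_per_deg))
    if scene.meta.get("background") == "white":
        img = np.ones((n, n, 3))
    else:
        img = np.repeat(brown_noise(n, rng)[:, :, None], 3, axis=2)
    regions = sorted(scene.regions,
                     key=lambda r: _DRAW_ORDER.index(r.label)
                     if r.label in _DRAW_ORDER else -1)
    for r in regions:
        if r.label == "background_control":
            continue
        mask = rasterize(r.shape, scene.canvas_deg, px_per_deg)
        if r.label == "noise_patch":
            img[mask] = rng.uniform(size=(int(mask.sum()), 3))
        elif r.label == "outline":
            ring = mask & ~ndimage.binary_erosion(mask, iterations=max(1, int(px_per_deg // 3)))
            img[ring] = (0.1, 0.1, 0.1)
        else:
            img[mask] = _LABEL_COLORS[r.label]
    return img


# ---------------------------------------------------------------------------
# presentation protocols
# ---------------------------------------------------------------------------

@dataclass
class PresentationProtocol:
    """Events table plus the grid/timing parameters that produced it.

    ``events`` columns: trial, presentation_index (within trial), scene_id,
    grid_x, grid_y (deg; the image-centre position relative to fixation) and
    onset_ms.  The grid is centred on ``grid_center_deg`` — normally the
    population receptive-field centre.
    """

    events: pd.DataFrame
    grid_shape: tuple
    spacing_deg: float
    grid_center_deg: tuple
    reps: int
    on_ms: float = 100.0
    off_ms: float = 200.0
    iti_ms: float = 500.0

    @property
    def grid_x(self):
        nx = self.grid_shape[1]
        return self.grid_center_deg[0] + self.spacing_deg * (np.arange(nx) - (nx - 1) / 2)

    @property
    def grid_y(self):
        ny = self.grid_shape[0]
        return self.grid_center_deg[1] + self.spacing_deg * (np.arange(ny) - (ny - 1) / 2)

    @property
    def scene_ids(self):
        return sorted(self.events["scene_id"].unique())

    @property
    def n_trials(self):
        return int(self.events["trial"].nunique())

    @property
    def duration_ms(self):
        return float(self.events["onset_ms"].max() + self.on_ms + self.off_ms + self.iti_ms)

    def to_csv(self, path):
        self.events.to_csv(path, index=False)


def make_protocol(grid_shape, spacing_deg, grid_center_deg, scenes,
                  reps: int, seed: int, on_ms: float = 100.0,
                  off_ms: float = 200.0, images_per_trial: int = 3,
                  iti_ms: float = 500.0) -> PresentationProtocol:
    """Randomized presentation order: every (scene, grid position) pair occurs
    exactly ``reps`` times; presentations run ``images_per_trial`` to a trial
    with 100 ms ON / 200 ms OFF timing by default."""
    scene_ids = [s.scene_id if isinstance(s, SceneSpec) else str(s) for s in scenes]
    if not scene_ids:
        raise ValueError("scene list is empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    nx, ny = grid_shape[1], grid_shape[0]
    gx = grid_center_deg[0] + spacing_deg * (np.arange(nx) - (nx - 1) / 2)
    gy = grid_center_deg[1] + spacing_deg * (np.arange(ny) - (ny - 1) / 2)
    combos = [(sid, x, y) for sid in scene_ids for x in gx for y in gy]
    order = np.tile(np.arange(len(combos)), reps)
    rng = np.random.default_rng(seed)
    order = rng.permutation(order)
    period = on_ms + off_ms
    trial = np.arange(len(order)) // images_per_trial
    pres_idx = np.arange(len(order)) % images_per_trial
    onset = trial * (images_per_trial * period + iti_ms) + pres_idx * period
    events = pd.DataFrame({
        "trial": trial,
        "presentation_index": pres_idx,
        "scene_id": [combos[i][0] for i in order],
        "grid_x": [combos[i][1] for i in order],
        "grid_y": [combos[i][2] for i in order],
        "onset_ms": onset.astype(float),
    })
    return PresentationProtocol(events, grid_shape, float(spacing_deg),
                                tuple(grid_center_deg), int(reps), on_ms,
                                off_ms, iti_ms)
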