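"""Synthetic segmented agave-layer generator with known ground truth.

Emulates what the counter actually consumes: the plant-class layer of a
UAV orthomosaic at ~3 cm/px, not a photorealistic field. Plants are
near-circular blobs on a jittered row lattice (rows 3-4 m apart, plants
1.0-1.2 m apart along a row, crowns 1-2 m across, so a large plant can be
wider than the spacing — the source of the overlap problem). Degradations
mirror what real segmented layers show: small weed blobs off and on the
rows (future false positives), interior holes, and illumination dropouts
that erase part or all of a plant (future false negatives).

Every stochastic choice draws from one seeded generator in a fixed order,
so a spec + seed reproduces the identical image on any platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .detection_eval import GroundTruth
from .segmask_preprocess import SegmentedImage

__all__ = [
    "PLANT_RGB",
    "FieldSpec",
    "SyntheticField",
    "generate_field",
    "field_presets",
]

#: green-dominant plant color; any positive luminance survives binarization
PLANT_RGB = (0, 170, 0)


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and degradation parameters of a synthetic field.

    Distances are in pixels at the nominal 3 cm/px ground sampling:
    row_spacing 117 px = 3.5 m, plant_spacing 37 px = 1.1 m, plant radii
    16-33 px = crown diameters of about 1-2 m.
    """

    height_px: int = 600
    width_px: int = 600
    row_spacing_px: float = 117.0
    plant_spacing_px: float = 37.0
    plant_radius_px_range: tuple[float, float] = (16.0, 33.0)
    jitter_px: float = 2.0
    overlap_prob: float = 0.0
    weed_density_per_kpx: float = 0.0
    hole_prob: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.plant_radius_px_range
        if not 0 < lo <= hi:
            raise ValueError("plant radius range must satisfy 0 < min <= max")
        for name in ("overlap_prob", "hole_prob", "dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.row_spacing_px <= 0 or self.plant_spacing_px <= 0:
            raise ValueError("spacings must be positive")
        if self.jitter_px < 0 or self.weed_density_per_kpx < 0:
            raise ValueError("jitter and weed density must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FieldSpec":
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown FieldSpec keys: {sorted(unknown)}")
        if "plant_radius_px_range" in data:
            data["plant_radius_px_range"] = tuple(data["plant_radius_px_range"])
        return cls(**data)


@dataclass
class SyntheticField:
    """A generated layer image, its ground truth and the generating spec."""

    image: SegmentedImage
    gt: GroundTruth
    spec: FieldSpec

    @property
    def mask(self) -> np.ndarray:
        """Binary support of the plant-colored pixels."""
        return self.image.pixels.sum(axis=2) > 0


def _disk(mask: np.ndarray, cy: float, cx: float, r: float, value: bool) -> None:
    h, w = mask.shape
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    mask[y0:y1, x0:x1][inside] = value


def _plant_centers(spec: FieldSpec, rng: np.random.Generator):
    """Lay out rows, then walk each row enforcing the overlap flag pairwise.

    A plant flagged for overlap is pulled toward its left neighbor until
    their disks intersect; an unflagged plant is pushed right, if needed,
    until a 1-px gap separates them. Plants whose disk no longer fits in
    the image are dropped (they were never "planted").
    """
    rmax = spec.plant_radius_px_range[1]
    margin = rmax + spec.jitter_px + 1.0
    centers: list[tuple[float, float, float]] = []  # (row, col, radius)
    y = margin
    while y <= spec.height_px - margin:
        prev: tuple[float, float, float] | None = None
        x = margin
        while x <= spec.width_px - margin:
            r = rng.uniform(*spec.plant_radius_px_range)
            jy = rng.uniform(-spec.jitter_px, spec.jitter_px)
            jx = rng.uniform(-spec.jitter_px, spec.jitter_px)
            overlap = rng.random() < spec.overlap_prob
            cy, cx = y + jy, x + jx
            if prev is not None:
                py, px, pr = prev
                if overlap:
                    # pull in so the disks intersect but centers stay apart
                    cx = px + (pr + r) * rng.uniform(0.70, 0.95)
                elif cx - px < pr + r + 1.0:
                    cx = px + pr + r + 1.0
            if cx > spec.width_px - margin:
                break
            centers.append((cy, cx, r))
            prev = (cy, cx, r)
            x = max(cx, x) + spec.plant_spacing_px
        y += spec.row_spacing_px
    return centers


def generate_field(spec: FieldSpec) -> SyntheticField:
    """Render a segmented-layer image and its ground truth from a spec."""
    rng = np.random.default_rng(spec.seed)
    centers = _plant_centers(spec, rng)
    if not centers:
        raise ValueError(
            "lattice infeasible: no plant fits the image at these spacings"
        )
    h, w = spec.height_px, spec.width_px
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, r in centers:
        _disk(mask, cy, cx, r, True)

    # interior holes (filled by preprocessing; exercise the fill stage)
    for cy, cx, r in centers:
        if rng.random() < spec.hole_prob:
            hr = rng.uniform(1.0, max(1.5, 0.15 * r))
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max(0.0, r - hr - 2.0))
            _disk(mask, cy + off * np.sin(ang), cx + off * np.cos(ang), hr, False)

    # illumination dropout: erase an angular sector of the plant, or
    # occasionally the whole plant (a guaranteed false negative)
    for cy, cx, r in centers:
        if rng.random() < spec.dropout_prob:
            if rng.random() < 0.15:
                _disk(mask, cy, cx, r + 1.0, False)
                continue
            frac = rng.uniform(0.25, 0.6)
            a0 = rng.uniform(0, 2 * np.pi)
            a1 = a0 + frac * 2 * np.pi
            y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
            x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 1) ** 2
            ang = np.mod(np.arctan2(yy - cy, xx - cx) - a0, 2 * np.pi)
            mask[y0:y1, x0:x1][inside & (ang <= a1 - a0)] = False

    # weed speckle anywhere in the frame, radius 1-4 px
    n_weeds = rng.poisson(spec.weed_density_per_kpx * h * w / 1000.0)
    for _ in range(n_weeds):
        wy = rng.uniform(0, h)
        wx = rng.uniform(0, w)
        wr = rng.uniform(1.0, 4.0)
        _disk(mask, wy, wx, wr, True)

    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    pixels[mask] = PLANT_RGB
    gt = GroundTruth(np.array([(cy, cx) for cy, cx, _ in centers]))
    return SyntheticField(image=SegmentedImage(pixels), gt=gt, spec=spec)


def field_presets() -> dict[str, FieldSpec]:
    """Named specs emulating the three surveyed field types.

    field1: red-clay field, plants of many ages — wide size range, heavy
    along-row overlap, little weed. field2: rocky soil with illumination
    problems — moderate overlap, weeds, frequent dropouts. field3:
    homogeneous plantation — narrow size range, moderate overlap, weeds.
    """
    return {
        "field1": FieldSpec(
            height_px=700,
            width_px=800,
            plant_radius_px_range=(12.0, 33.0),
            overlap_prob=0.45,
            weed_density_per_kpx=0.01,
            hole_prob=0.20,
            dropout_prob=0.04,
        ),
        "field2": FieldSpec(
            height_px=700,
            width_px=800,
            plant_radius_px_range=(14.0, 30.0),
            overlap_prob=0.25,
            weed_density_per_kpx=0.03,
            hole_prob=0.20,
            dropout_prob=0.20,
        ),
        "field3": FieldSpec(
            height_px=700,
            width_px=800,
            plant_radius_px_range=(20.0, 26.0),
            overlap_prob=0.30,
            weed_density_per_kpx=0.03,
            hole_prob=0.10,
            dropout_prob=0.04,
        ),
    }


def get_preset(name: str, seed: int | None = None) -> FieldSpec:
    """Look up a preset by name, optionally re-seeding it."""
    presets = field_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    spec = presets[name]
    return spec if seed is None else replace(spec, seed=seed)
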