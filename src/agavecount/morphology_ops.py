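"""Flat binary structuring elements and morphological operators.

The counting pipeline uses exactly two structuring elements: a 3x3 square
(for the opening/closing that separates touching plants) and a city-block
diamond of radius 2 (for the iterative erosion of the counting loop).
Both are flat, origin-centered and point-symmetric.

Border policy: pixels outside the image are background for *both* erosion
and dilation, so objects touching the frame erode from the border like
interior objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "StructuringElement",
    "make_se",
    "se_from_string",
    "SQUARE3",
    "DIAMOND2",
    "erode",
    "dilate",
    "open_mask",
    "close_mask",
    "separate_objects",
]


@dataclass(frozen=True)
class StructuringElement:
    """An origin-centered flat structuring element.

    ``size`` is the side length for squares (odd) and the radius (maximum
    city-block distance from the center) for diamonds.
    """

    shape: str
    size: int
    footprint: np.ndarray = field(repr=False, compare=False)

    @property
    def offsets(self) -> frozenset[tuple[int, int]]:
        """(dy, dx) offsets of the element, origin-centered."""
        r = self.footprint.shape[0] // 2
        ys, xs = np.nonzero(self.footprint)
        return frozenset(zip((ys - r).tolist(), (xs - r).tolist()))

    def __post_init__(self) -> None:
        fp = np.ascontiguousarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        h, w = fp.shape
        if h != w or h % 2 == 0:
            raise ValueError("footprint must be square with odd side")
        if not fp[h // 2, w // 2]:
            raise ValueError("structuring element must contain its origin")
        if not np.array_equal(fp, fp[::-1, ::-1]):
            raise ValueError("structuring element must be point-symmetric")

    def __str__(self) -> str:
        return f"{self.shape}:{self.size}"


def make_se(shape: str, size: int) -> StructuringElement:
    """Build a structuring element.

    ``("square", n)`` with n odd gives the full n x n block;
    ``("diamond", r)`` gives all offsets with ``|dy| + |dx| <= r``
    (the convention of mainstream morphology toolboxes, 13 pixels for r=2).
    ``("diamond", 0)`` is the identity element.
    """
    if shape == "square":
        if size < 1 or size % 2 == 0:
            raise ValueError(f"square size must be odd and >= 1, got {size}")
        fp = np.ones((size, size), dtype=bool)
    elif shape == "diamond":
        if size < 0:
            raise ValueError(f"diamond radius must be >= 0, got {size}")
        r = size
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        fp = np.abs(yy) + np.abs(xx) <= r
    else:
        raise ValueError(f"unknown structuring element shape {shape!r}")
    return StructuringElement(shape=shape, size=size, footprint=fp)


def se_from_string(text: str) -> StructuringElement:
    """Parse a ``"shape:size"`` string such as ``"square:3"`` or ``"diamond:2"``."""
    try:
        shape, _, size = text.partition(":")
        return make_se(shape.strip(), int(size))
    except ValueError as exc:
        raise ValueError(f"bad structuring element spec {text!r}: {exc}") from exc


SQUARE3 = make_se("square", 3)
DIAMOND2 = make_se("diamond", 2)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool, copy=False)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion; out-of-image pixels count as background."""
    return ndi.binary_erosion(_as_bool(mask), structure=se.footprint, border_value=0)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation; out-of-image pixels count as background."""
    return ndi.binary_dilation(_as_bool(mask), structure=se.footprint, border_value=0)


def open_mask(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological opening (erosion then dilation with the same element)."""
    return dilate(erode(mask, se), se)


def close_mask(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological closing (dilation then erosion with the same element)."""
    return erode(dilate(mask, se), se)


def separate_objects(
    ic: np.ndarray, se: StructuringElement = SQUARE3
) -> np.ndarray:
    """Opening followed by closing of the cleaned mask.

    The opening removes thin necks and protrusions that bridge adjacent
    plants; the closing then recovers plant-body pixels the opening
    distorted. The order matters: closing first would weld overlapping
    plants together before the opening could cut them apart.
    """
    return close_mask(open_mask(ic, se), se)
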