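"""Preprocessing: segmented RGB crop layer -> cleaned binary mask.

The input is the plant-class layer produced by an upstream segmentation of
a UAV orthomosaic (plant pixels in color, background black, ~3 cm/px).
The stages are: luminance conversion, binarization at strictly positive
gray level, removal of isolated specks, and filling of interior holes.
The result is the mask all later morphology operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

__all__ = [
    "GRAY_WEIGHTS",
    "SegmentedImage",
    "GrayImage",
    "rgb_to_gray",
    "binarize",
    "clean_mask",
    "fill_holes",
    "preprocess",
]

#: ITU-R BT.601 luma weights for (R, G, B).
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class SegmentedImage:
    """An RGB crop-layer raster with its ground sampling distance.

    ``pixels`` is H x W x 3, channel values in 0..255.  ``gsd_cm_per_px``
    is the ground size of one pixel (defaults to the 3 cm of a ~60 m
    UAV flight with a standard RGB sensor).
    """

    pixels: np.ndarray
    gsd_cm_per_px: float = 3.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if self.gsd_cm_per_px <= 0:
            raise ValueError("gsd_cm_per_px must be positive")
        self.pixels = px

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """A floating-point grayscale raster with values in [0, 255]."""

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected H x W raster, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("empty image")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        self.pixels = px


def rgb_to_gray(img: SegmentedImage | np.ndarray) -> GrayImage:
    """Weighted luminance I = 0.299 R + 0.587 G + 0.114 B.

    Kept in floating point: no rounding happens before thresholding, so a
    dim but nonzero plant pixel is never lost.
    """
    px = img.pixels if isinstance(img, SegmentedImage) else SegmentedImage(img).pixels
    if px.size == 0:
        raise ValueError("empty image")
    w = np.asarray(GRAY_WEIGHTS)
    return GrayImage(px.astype(float) @ w)


def binarize(gray: GrayImage | np.ndarray) -> np.ndarray:
    """Foreground wherever the gray level is strictly positive."""
    px = gray.pixels if isinstance(gray, GrayImage) else GrayImage(gray).pixels
    return px > 0


def clean_mask(mask: np.ndarray, min_area: int = 2) -> np.ndarray:
    """Drop foreground components (8-connected) with area < ``min_area``.

    The default of 2 removes exactly the isolated single pixels left by
    the upstream segmentation; larger speck removal is available through
    ``min_area`` but is not part of the default pipeline.
    """
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    m = np.asarray(mask, dtype=bool)
    if min_area == 1:
        return m.copy()
    # max_size removes components with area <= max_size, hence area < min_area
    return skmorph.remove_small_objects(m, max_size=min_area - 1, connectivity=2)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the image border.

    Background connectivity is 4-connected (the dual of the 8-connected
    foreground), so a diagonal chain of background pixels does not count
    as an escape route out of a plant.
    """
    m = np.asarray(mask, dtype=bool)
    # default cross-shaped structure = 4-connected background fill
    return ndi.binary_fill_holes(m)


def preprocess(img: SegmentedImage | np.ndarray, min_area: int = 2) -> np.ndarray:
    """Full preprocessing chain: gray -> binarize -> clean -> fill.

    Returns the cleaned mask Ic that the object-separation and counting
    stages consume.
    """
    return fill_holes(clean_mask(binarize(rgb_to_gray(img)), min_area=min_area))
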