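import numpy as np
import pytest


def draw_disk(shape, center, radius, mask=None):
    """Paint a filled circle into a boolean raster (creates one if needed)."""
    m = np.zeros(shape, dtype=bool) if mask is None else mask
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    m |= (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    return m


def brute_force_erode(mask, offsets):
    """Literal definition of erosion: every offset must land on foreground."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                    ok = False
                    break
            out[y, x] = ok
    return out


def brute_force_dilate(mask, offsets):
    """Literal definition of dilation: any reflected offset on foreground."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            hit = False
            for dy, dx in offsets:
                yy, xx = y - dy, x - dx
                if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                    hit = True
                    break
            out[y, x] = hit
    return out


def random_blob_mask(rng, shape=(32, 32), p=0.4):
    """Random binary mask with some spatial correlation (blobby, not salt)."""
    noise = rng.random(shape)
    # box-blur the noise so thresholding yields connected structures
    k = np.ones((3, 3)) / 9.0
    from scipy.signal import convolve2d

    smooth = convolve2d(noise, k, mode="same", boundary="symm")
    return smooth < p


@pytest.fixture
def rng():
    return np.random.default_rng(20201102)
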