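"""Frame preprocessing: green channel, glare mask, smoothing, CLAHE.

Laparoscopic frames carry strong specular highlights (glare) and dark
instrument shadows where descriptors are unreliable. Feature detection
therefore runs on the green channel — the best-contrasted channel for
tissue — restricted to a glare mask that removes both intensity extremes,
after box-filter denoising and contrast-limited adaptive histogram
equalization (CLAHE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_adapthist

from ._kernels import elliptical_footprint
from .io_formats import FrameImage

__all__ = [
    "MonoImage",
    "GlareMask",
    "extract_green",
    "compute_glare_mask",
    "smooth_and_equalize",
    "preprocess_frame",
]

# a MonoImage is a plain (H, W) uint8 array
MonoImage = np.ndarray


@dataclass(frozen=True)
class GlareMask:
    """Usable-pixel mask after intensity banding and 5x5 elliptical erosion.

    ``mask`` is True where features may be detected. ``lower_frac`` and
    ``upper_frac`` are fractions of the 8-bit maximum value range: with the
    defaults 0.20/0.80 a pixel is kept (pre-erosion) iff 51 < v < 204.
    """

    mask: np.ndarray  # (H, W) bool
    lower_frac: float = 0.20
    upper_frac: float = 0.80
    erosion_size: int = 5


def extract_green(frame: FrameImage) -> MonoImage:
    """Return the frame's green channel, unchanged."""
    if frame.pixels.ndim != 3 or frame.pixels.shape[2] != 3:
        raise ValueError("extract_green needs a 3-channel RGB frame")
    return frame.pixels[:, :, 1].copy()


def compute_glare_mask(
    mono: MonoImage,
    lower_frac: float = 0.20,
    upper_frac: float = 0.80,
    mode: str = "range",
    erosion_size: int = 5,
) -> GlareMask:
    """Mask glare and dark areas of a single-channel image.

    Pixels with intensity at or below ``lower_frac`` and at or above
    ``upper_frac`` of the maximum value range (``mode='range'``, thresholds
    51 and 204 on 8-bit data) are removed, then the remaining area is eroded
    with an elliptical 5x5 structuring element. ``mode='percentile'``
    computes the thresholds from the image's own intensity distribution
    instead. Pixels outside the image count as unusable, so the mask also
    shrinks at the frame border.
    """
    if not 0 <= lower_frac < upper_frac <= 1:
        raise ValueError("need 0 <= lower_frac < upper_frac <= 1")
    if mode == "range":
        lo, hi = lower_frac * 255.0, upper_frac * 255.0
    elif mode == "percentile":
        lo = float(np.percentile(mono, lower_frac * 100))
        hi = float(np.percentile(mono, upper_frac * 100))
    else:
        raise ValueError(f"unknown glare mode {mode!r}")
    kept = (mono > lo) & (mono < hi)
    eroded = ndimage.binary_erosion(
        kept, structure=elliptical_footprint(erosion_size), border_value=0
    )
    return GlareMask(mask=eroded, lower_frac=lower_frac, upper_frac=upper_frac,
                     erosion_size=erosion_size)


def smooth_and_equalize(
    mono: MonoImage, box_size: int = 5, clahe_tiles: int = 8, clahe_clip: float = 2.0
) -> MonoImage:
    """Box-filter then CLAHE a single-channel 8-bit image.

    The normalized ``box_size`` x ``box_size`` box filter uses border
    replication. CLAHE uses a ``clahe_tiles`` x ``clahe_tiles`` tile grid and
    ``clahe_clip`` on the conventional per-bin scale (a clip of 2.0 limits
    each of the 256 histogram bins to twice the uniform count; internally
    converted to the normalized clip limit of the underlying implementation).
    """
    h, w = mono.shape
    if h < clahe_tiles or w < clahe_tiles:
        raise ValueError(f"image {h}x{w} smaller than one {clahe_tiles}x{clahe_tiles} CLAHE tile grid")
    smoothed = ndimage.uniform_filter(mono.astype(np.float64), size=box_size, mode="nearest")
    smoothed_u8 = np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)
    kernel = (max(h // clahe_tiles, 1), max(w // clahe_tiles, 1))
    eq = equalize_adapthist(smoothed_u8, kernel_size=kernel, clip_limit=clahe_clip / 256.0, nbins=256)
    return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)


def preprocess_frame(
    frame: FrameImage,
    lower_frac: float = 0.20,
    upper_frac: float = 0.80,
    glare_mode: str = "range",
    box_size: int = 5,
    clahe_tiles: int = 8,
    clahe_clip: float = 2.0,
) -> tuple[MonoImage, GlareMask]:
    """Full preprocessing of one frame.

    Returns the smoothed + equalized green channel and the glare mask. The
    mask is computed on the raw green channel, not the equalized one, so the
    intensity band refers to the original photometry.
    """
    green = extract_green(frame)
    mask = compute_glare_mask(green, lower_frac, upper_frac, mode=glare_mode)
    mono = smooth_and_equalize(green, box_size=box_size, clahe_tiles=clahe_tiles,
                               clahe_clip=clahe_clip)
    return mono, mask
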