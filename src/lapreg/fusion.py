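"""Per-pixel fusion of candidate warps and the safe-display mask.

For visualization, the start frame is warped by the global homography and by
every valid HMA region homography separately. Photometric error images
(closed absolute green-channel differences against the current frame) rank
the candidates per pixel; the lowest-error candidate wins each pixel. The
combined minimum-error image then drives a binary display mask: pixels whose
residual error exceeds 10% of the intensity range are suppressed (the
original current frame is shown there instead), after a 35 px binary median
removes isolated decisions. The flow degrades safely — with no trustworthy
candidate the viewer simply sees the live frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._kernels import binary_median, elliptical_footprint
from .io_formats import FrameImage
from .transforms import HomographyTransform, RegionTransform, WarpResult

__all__ = [
    "CandidateWarp",
    "FusionResult",
    "validate_region",
    "build_error_image",
    "fuse_candidates",
    "build_display_mask",
    "compose_output",
]


@dataclass
class CandidateWarp:
    warp: WarpResult
    error_image: np.ndarray  # (H, W) uint8
    label: str  # "SH", "HMA-0", ..., "MLS"


@dataclass
class FusionResult:
    fused_image: np.ndarray  # (H, W, 3) uint8
    source_index: np.ndarray  # (H, W) int, argmin candidate per pixel
    combined_error: np.ndarray  # (H, W) uint8 pointwise minimum
    labels: list[str]
    display_mask: np.ndarray | None = None  # True = show fused pixel


def validate_region(
    region: RegionTransform,
    H_global: HomographyTransform,
    image_size: tuple[int, int],
    min_area_frac: float = 0.02,
    max_h_diff: float = 50.0,
) -> bool:
    """Accept an HMA region for fusion.

    Valid iff (a) its support polygon covers more than ``min_area_frac`` of
    the image area and (b) the entrywise sum of absolute differences between
    the local homography and the global one (both normalized to H[2,2] = 1)
    is below ``max_h_diff``. Near-degenerate local homographies differ wildly
    from the global one and are rejected by (b).
    """
    Hl, Hg = region.H_local.H, H_global.H
    for H in (Hl, Hg):
        if abs(H[2, 2] - 1.0) > 1e-9:
            raise ValueError("homography not normalized to H[2,2] = 1")
    W, H_img = image_size
    if region.area <= min_area_frac * W * H_img:
        return False
    return float(np.abs(Hl - Hg).sum()) < max_h_diff


def build_error_image(
    warp: WarpResult, current: FrameImage, closing_size: int = 35,
    use_green: bool = True,
) -> np.ndarray:
    """Closed absolute-difference error of a warped start frame.

    Absolute difference of the green channels, forced to 255 where the warp
    has no source pixel (so other candidates or the display mask win there),
    then a grayscale morphological closing with an elliptical structuring
    element (border: replicate). Closing fills thin low-error seams so that
    region selection is spatially coherent.
    """
    cur = current.pixels[:, :, 1] if use_green else current.pixels.mean(-1)
    wim = warp.image[:, :, 1] if warp.image.ndim == 3 else warp.image
    if wim.shape != cur.shape:
        raise ValueError("warp/current shape mismatch")
    diff = np.abs(wim.astype(np.int16) - cur.astype(np.int16)).astype(np.uint8)
    diff[~warp.validity] = 255
    fp = elliptical_footprint(closing_size)
    closed = ndimage.grey_closing(diff, footprint=fp, mode="nearest")
    return closed.astype(np.uint8)


def fuse_candidates(candidates: list[CandidateWarp]) -> FusionResult:
    """Select, per pixel, the candidate with the lowest error.

    Ties go to the earliest candidate in list order (the globally trusted
    single homography is conventionally first).
    """
    if not candidates:
        raise ValueError("need at least one candidate warp")
    shape = candidates[0].error_image.shape
    for c in candidates:
        if c.error_image.shape != shape or c.warp.image.shape[:2] != shape:
            raise ValueError("candidate shapes differ")
    errors = np.stack([c.error_image for c in candidates])  # (C, H, W)
    source_index = errors.argmin(axis=0)  # first occurrence wins ties
    combined = np.take_along_axis(errors, source_index[None], axis=0)[0]
    images = np.stack([
        c.warp.image if c.warp.image.ndim == 3 else np.stack([c.warp.image] * 3, -1)
        for c in candidates
    ])  # (C, H, W, 3)
    fused = np.take_along_axis(images, source_index[None, :, :, None], axis=0)[0]
    return FusionResult(
        fused_image=fused.astype(np.uint8),
        source_index=source_index,
        combined_error=combined.astype(np.uint8),
        labels=[c.label for c in candidates],
    )


def build_display_mask(
    combined_error: np.ndarray,
    threshold_frac: float = 0.10,
    median_size: int = 35,
) -> np.ndarray:
    """Suppression mask from the combined error image.

    A pixel is marked for suppression when its error strictly exceeds
    ``threshold_frac`` of the 8-bit range (10% of 255 = 25.5, i.e. >= 26 on
    integer data); the binary mask is then cleaned with a ``median_size``
    square majority-vote median. Returns True where the overlay must NOT be
    shown.
    """
    raw = combined_error.astype(float) > threshold_frac * 255.0
    return binary_median(raw, median_size)


def compose_output(fusion: FusionResult, current: FrameImage) -> FrameImage:
    """Splice the fused overlay with the live frame via the display mask.

    Where ``fusion.display_mask`` is True the fused pixel is shown; masked
    pixels fall back to the original current frame. A fusion without a
    display mask shows the fused image everywhere.
    """
    if fusion.fused_image.shape != current.pixels.shape:
        raise ValueError("fusion/current shape mismatch")
    if fusion.display_mask is None:
        return FrameImage(fusion.fused_image.copy(), current.frame_index)
    out = np.where(fusion.display_mask[:, :, None], fusion.fused_image, current.pixels)
    return FrameImage(out.astype(np.uint8), current.frame_index)
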