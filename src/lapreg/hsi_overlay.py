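"""Augmentation of registered video with a static physiological map.

Hyperspectral imaging yields a static tissue-oxygenation (StO2) map on its
own sensor's pixel grid. Two transforms bring it onto the live video: a
one-time sensor calibration homography (color and HSI sensors are rigidly
mounted, so the mapping is fixed per device and fitted once from manually
annotated point pairs), and the per-frame registration homography from the
start frame to the current frame. The map is rendered as a perceptually
ordered false-color image and alpha-blended over the grayscale live frame;
unreliable pixels (display mask) and pixels the warped map does not cover
show the untouched live frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.color import rgb2gray
from skimage.transform import ProjectiveTransform

from .io_formats import FrameImage
from .transforms import (
    DeformationField,
    EstimationError,
    HomographyTransform,
    warp_image,
)

__all__ = [
    "SensorCalibration",
    "PhysioMap",
    "calibrate_sensors",
    "colorize",
    "render_overlay",
]

DEFAULT_COLORMAP = "viridis"


@dataclass
class SensorCalibration:
    """Fixed homography from HSI-sensor coordinates to color-sensor coordinates."""

    H_cal: HomographyTransform
    point_pairs: tuple[np.ndarray, np.ndarray]  # (hsi_xy, color_xy)
    rms_residual: float


@dataclass
class PhysioMap:
    """A physiological quantity (e.g. StO2 fraction) on the HSI pixel grid."""

    values: np.ndarray  # (H', W') float in [0, 1]; NaN = no data
    colormap_id: str = DEFAULT_COLORMAP
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        finite = np.isfinite(self.values)
        clipped = np.where(finite, np.clip(self.values, 0.0, 1.0), np.nan)
        self.values = clipped
        if self.valid_mask is None:
            self.valid_mask = finite
        else:
            self.valid_mask = self.valid_mask & finite


def calibrate_sensors(pairs: list[tuple[np.ndarray, np.ndarray]] |
                      tuple[np.ndarray, np.ndarray]) -> SensorCalibration:
    """Fit the sensor homography from annotated point pairs.

    The annotations are trusted, so a least-squares normalized DLT over ALL
    pairs (no RANSAC) is appropriate; the RMS residual quantifies annotation
    quality. At least 4 non-collinear pairs are required (25 is the typical
    annotation effort).
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and np.asarray(pairs[0]).ndim == 2:
        hsi_xy = np.asarray(pairs[0], float)
        color_xy = np.asarray(pairs[1], float)
    else:
        hsi_xy = np.array([p[0] for p in pairs], float)
        color_xy = np.array([p[1] for p in pairs], float)
    if len(hsi_xy) < 4:
        raise EstimationError(f"need >= 4 calibration pairs, got {len(hsi_xy)}")
    tf = ProjectiveTransform.from_estimate(hsi_xy, color_xy)
    if not tf:
        raise EstimationError("degenerate calibration point configuration")
    H = HomographyTransform(tf.params)
    mapped = H.apply(hsi_xy)
    rms = float(np.sqrt(np.mean(np.sum((mapped - color_xy) ** 2, axis=1))))
    return SensorCalibration(H_cal=H, point_pairs=(hsi_xy, color_xy), rms_residual=rms)


def colorize(pmap: PhysioMap) -> tuple[np.ndarray, np.ndarray]:
    """False-color the map with its perceptual colormap.

    Returns (rgb uint8, valid mask); 0 and 1 hit the colormap endpoints and
    NaN values are invalid (rendered transparent by the overlay).
    """
    cmap = colormaps[pmap.colormap_id]
    vals = np.where(pmap.valid_mask, np.nan_to_num(pmap.values, nan=0.0), 0.0)
    rgb = cmap(vals)[:, :, :3]
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8), pmap.valid_mask.copy()


def render_overlay(
    current: FrameImage,
    frame_transform: HomographyTransform | DeformationField | None,
    pmap: PhysioMap,
    cal: SensorCalibration,
    alpha: float = 0.5,
    display_mask: np.ndarray | None = None,
) -> FrameImage:
    """Overlay the physiological map on the registered live frame.

    The colorized map is warped by the composition frame_transform ∘ H_cal
    into current-frame geometry and alpha-blended
    (``out = round(alpha * color + (1 - alpha) * gray)``) over the grayscale
    current frame. Pixels outside the warped map, with invalid map data, or
    where ``display_mask`` is False show the untouched current frame.
    """
    h, w = current.shape
    color_rgb, map_valid = colorize(pmap)
    vimg = map_valid.astype(np.uint8) * 255

    if frame_transform is None:
        total = cal.H_cal
    elif isinstance(frame_transform, HomographyTransform):
        total = frame_transform.compose(cal.H_cal)
    else:  # deformation field composes by chained warping
        pre = warp_image(color_rgb, cal.H_cal, output_shape=(h, w))
        prev = warp_image(vimg, cal.H_cal, output_shape=(h, w))
        color_rgb = pre.image
        vimg = np.where(pre.validity, prev.image, 0)
        total = frame_transform
    wr = warp_image(color_rgb, total, output_shape=(h, w))
    wv = warp_image(vimg, total, output_shape=(h, w))
    map_ok = wr.validity & (wv.image > 127)
    if display_mask is not None:
        map_ok &= display_mask

    gray = np.clip(np.rint(rgb2gray(current.pixels) * 255.0), 0, 255).astype(np.uint8)
    gray3 = np.stack([gray] * 3, axis=-1).astype(np.float64)
    blended = np.rint(alpha * wr.image.astype(np.float64) + (1.0 - alpha) * gray3)
    out = np.where(map_ok[:, :, None], np.clip(blended, 0, 255),
                   current.pixels).astype(np.uint8)
    return FrameImage(out, current.frame_index)
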