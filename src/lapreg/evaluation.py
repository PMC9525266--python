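"""Quantitative evaluation of registration against landmark ground truth.

A *scene* starts at a chosen start frame and registers every subsequent
frame back to it. For each frame, every landmark visible in both the start
and the current frame contributes:

* **RE** — reprojection error, the Euclidean distance in pixels between the
  transformed start-frame landmark and its annotated position in the
  current frame;
* **nRE** — RE normalized by that landmark's own moved distance between the
  two frames, so that doing nothing (identity transform) scores exactly 1;
* **SSIM** — structural similarity between the current frame and the warped
  start frame (grayscale, Gaussian-weighted 11x11 window, sigma 1.5).

Means are taken per frame (over landmarks), per scene (over frames), and
overall (over scenes, equally weighted). Quality gating and display-mask
postprocessing are deliberately not applied here — the metrics measure the
raw estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.metrics import structural_similarity

from .features import detect_describe, match_features
from .io_formats import AnnotationSet, FrameImage, RunConfig, read_cvat_xml, read_frames
from .preprocess import preprocess_frame
from .transforms import (
    DeformationField,
    EstimationError,
    HomographyTransform,
    estimate_mls_field,
    estimate_single_homography,
    warp_image,
)

__all__ = [
    "SceneSpec",
    "PointError",
    "RegistrationMetrics",
    "Table1Row",
    "point_errors",
    "compute_ssim",
    "run_scene",
    "aggregate_scenes",
    "ground_truth_transform",
    "make_method",
    "reproduce_reference_benchmark",
]

ZERO_MOTION_EPS = 1e-6


@dataclass(frozen=True)
class SceneSpec:
    """One evaluation scene: register (start, last] back to the start frame."""

    start_frame: int
    last_frame: int = 749
    frame_step: int = 1  # evaluate every frame_step-th frame
    min_annotations_for_plot: int = 15

    def __post_init__(self) -> None:
        if self.start_frame >= self.last_frame:
            raise ValueError("start_frame must precede last_frame")

    def frames(self) -> list[int]:
        return list(range(self.start_frame + self.frame_step,
                          self.last_frame + 1, self.frame_step))


@dataclass(frozen=True)
class PointError:
    track_id: int
    re: float  # px
    moved: float  # px
    nre: float | None  # None when the landmark did not move


@dataclass
class RegistrationMetrics:
    """Per-frame and scene-level registration accuracy."""

    per_frame: pd.DataFrame  # frame_index, mean_re, mean_nre, ssim, n_points, flagged
    scene_mean_re: float
    scene_mean_nre: float
    scene_mean_ssim: float
    start_frame: int = 0


@dataclass(frozen=True)
class Table1Row:
    mean_re: float
    mean_nre: float
    mean_ssim: float
    n_scenes: int


def _apply_transform(transform, points: np.ndarray) -> np.ndarray:
    if transform is None:
        return np.asarray(points, float).copy()
    if isinstance(transform, HomographyTransform):
        return transform.apply(points)
    if isinstance(transform, DeformationField):
        return transform.apply(points)
    if callable(transform):
        return np.asarray(transform(points), float)
    raise TypeError(f"cannot apply {type(transform).__name__} to points")


def point_errors(
    transform,
    annotations: AnnotationSet,
    start_frame: int,
    current_frame: int,
    zero_motion: str = "exclude",
) -> list[PointError]:
    """Per-landmark reprojection errors for one frame pair.

    Only landmarks visible in both frames contribute. A landmark whose own
    motion is below 1e-6 px has no meaningful normalization; with
    ``zero_motion='exclude'`` its nRE is None (excluded from nRE means),
    with ``'epsilon'`` the moved distance is floored at 1e-6.
    """
    ids, p_start, p_cur = annotations.covisible_pairs(start_frame, current_frame)
    if len(ids) == 0:
        return []
    mapped = _apply_transform(transform, p_start)
    re = np.linalg.norm(mapped - p_cur, axis=1)
    moved = np.linalg.norm(p_start - p_cur, axis=1)
    out = []
    for tid, r, m in zip(ids, re, moved):
        if m < ZERO_MOTION_EPS:
            nre = None if zero_motion == "exclude" else float(r) / ZERO_MOTION_EPS
        else:
            nre = float(r) / float(m)
        out.append(PointError(int(tid), float(r), float(m), nre))
    return out


def compute_ssim(reference: np.ndarray, test: np.ndarray) -> float:
    """SSIM between two 8-bit single-channel images.

    Gaussian-weighted window (sigma 1.5, 11x11 — reduced to the largest odd
    size that fits for tiny images), K1 = 0.01, K2 = 0.03, data range 255.
    """
    if reference.shape != test.shape:
        raise ValueError("SSIM inputs must share a shape")
    win = min(11, reference.shape[0], reference.shape[1])
    if win % 2 == 0:
        win -= 1
    return float(structural_similarity(
        reference.astype(np.float64), test.astype(np.float64),
        win_size=win, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, data_range=255.0,
    ))


def _to_gray_u8(frame: FrameImage) -> np.ndarray:
    return np.clip(np.rint(rgb2gray(frame.pixels) * 255.0), 0, 255).astype(np.uint8)


def _frame_ssim(start: FrameImage, current: FrameImage, transform,
                fill: str = "mean") -> float:
    if transform is None:
        warped_gray = _to_gray_u8(start)
        validity = np.ones(start.shape, bool)
    else:
        wr = warp_image(start.pixels, transform)
        warped_gray = np.clip(np.rint(rgb2gray(wr.image) * 255.0), 0, 255).astype(np.uint8)
        validity = wr.validity
    cur_gray = _to_gray_u8(current)
    if fill == "mean":
        warped_gray = np.where(validity, warped_gray, int(round(cur_gray.mean())))
    elif fill == "current":
        warped_gray = np.where(validity, warped_gray, cur_gray)
    # fill == "zero": leave the zeros from warping in place
    return compute_ssim(cur_gray, warped_gray.astype(np.uint8))


def ground_truth_transform(
    annotations: AnnotationSet,
    start_frame: int,
    current_frame: int,
    mode: str = "SH",
    threshold: float = 5.0,
    seed: int = 17,
    image_size: tuple[int, int] | None = None,
    grid_density: float = 0.2,
    alpha: float = 1.0,
):
    """Manual-annotation transform: fit directly to the landmark pairs.

    ``mode='SH'`` fits a RANSAC homography (threshold 5 px) to the
    co-visible landmark pairs; ``mode='MLS'`` builds a deformation field
    with the pairs as control points. Raises EstimationError when too few
    landmarks are co-visible.
    """
    ids, p_start, p_cur = annotations.covisible_pairs(start_frame, current_frame)
    if mode == "SH":
        if len(ids) < 4:
            raise EstimationError(f"only {len(ids)} co-visible landmarks; need 4")
        return estimate_single_homography(p_start, p_cur, threshold=threshold, seed=seed)
    if mode == "MLS":
        if len(ids) < 3:
            raise EstimationError(f"only {len(ids)} co-visible landmarks; need 3")
        size = image_size or annotations.image_size
        return estimate_mls_field(p_start, p_cur, size, grid_density=grid_density,
                                  alpha=alpha)
    raise ValueError(f"unknown ground-truth mode {mode!r}")


def make_method(name: str, annotations: AnnotationSet | None = None,
                config: RunConfig | None = None) -> Callable:
    """Build a registration method callable ``f(start_frame, current_frame) -> transform``.

    Names: ``identity``; ``manual:sh`` / ``manual:mls`` (fit to ground-truth
    landmarks); ``orb:sh`` / ``orb:mls`` (full feature pipeline with the
    configured detector).
    """
    cfg = config or RunConfig()
    name = name.lower()
    if name == "identity":
        return lambda start, current: None
    if name.startswith("manual:"):
        mode = name.split(":", 1)[1].upper()
        if annotations is None:
            raise ValueError("manual methods need annotations")

        def manual(start: FrameImage, current: FrameImage):
            return ground_truth_transform(
                annotations, start.frame_index, current.frame_index, mode=mode,
                threshold=cfg.ransac_threshold, seed=cfg.seed,
                grid_density=cfg.mls_grid_density, alpha=cfg.mls_alpha,
            )

        return manual
    if name.startswith("orb:"):
        mode = name.split(":", 1)[1].upper()
        cache: dict[int, object] = {}

        def feature_method(start: FrameImage, current: FrameImage):
            if start.frame_index not in cache:
                mono_s, mask_s = preprocess_frame(start)
                cache[start.frame_index] = detect_describe(mono_s, mask_s)
            kp_s = cache[start.frame_index]
            mono_c, mask_c = preprocess_frame(current)
            kp_c = detect_describe(mono_c, mask_c)
            matches = match_features(kp_s, kp_c, retain_frac=cfg.match_retain_frac)
            if len(matches) < 4:
                raise EstimationError("too few matches")
            if mode == "SH":
                return estimate_single_homography(
                    matches.src_xy, matches.dst_xy, threshold=cfg.ransac_threshold,
                    seed=cfg.seed, max_trials=cfg.ransac_max_trials,
                    confidence=cfg.ransac_confidence,
                )
            if mode == "MLS":
                w = current.pixels.shape[1]
                h = current.pixels.shape[0]
                return estimate_mls_field(matches.src_xy, matches.dst_xy, (w, h),
                                          grid_density=cfg.mls_grid_density,
                                          alpha=cfg.mls_alpha)
            raise ValueError(f"unknown feature mode {mode!r}")

        return feature_method
    raise ValueError(f"unknown method {name!r}")


def run_scene(
    frames: list[FrameImage],
    annotations: AnnotationSet,
    method: str | Callable,
    scene: SceneSpec,
    compute_image_ssim: bool = True,
    zero_motion: str = "exclude",
    ssim_fill: str = "mean",
) -> RegistrationMetrics:
    """Evaluate one method over one scene.

    ``frames`` must contain the start frame and all evaluated frames (by
    ``frame_index``). A frame on which the method fails is recorded with the
    identity transform and flagged. No quality gate or display-mask
    postprocessing runs here.
    """
    by_index = {f.frame_index: f for f in frames}
    if scene.start_frame not in by_index:
        raise ValueError(f"start frame {scene.start_frame} not in frames")
    start = by_index[scene.start_frame]
    fn = make_method(method, annotations) if isinstance(method, str) else method

    rows = []
    for fi in scene.frames():
        if fi not in by_index:
            continue
        current = by_index[fi]
        flagged = False
        try:
            transform = fn(start, current)
        except EstimationError:
            transform = None
            flagged = True
        errs = point_errors(transform, annotations, scene.start_frame, fi,
                            zero_motion=zero_motion)
        mean_re = float(np.mean([e.re for e in errs])) if errs else np.nan
        nres = [e.nre for e in errs if e.nre is not None]
        mean_nre = float(np.mean(nres)) if nres else np.nan
        ssim = (_frame_ssim(start, current, transform, fill=ssim_fill)
                if compute_image_ssim else np.nan)
        rows.append({
            "frame_index": fi, "mean_re": mean_re, "mean_nre": mean_nre,
            "ssim": ssim, "n_points": len(errs), "flagged": flagged,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("scene produced no evaluated frames")
    return RegistrationMetrics(
        per_frame=df,
        scene_mean_re=float(df["mean_re"].mean(skipna=True)),
        scene_mean_nre=float(df["mean_nre"].mean(skipna=True)),
        scene_mean_ssim=float(df["ssim"].mean(skipna=True)),
        start_frame=scene.start_frame,
    )


def aggregate_scenes(metrics: list[RegistrationMetrics]) -> Table1Row:
    """Overall means across scenes (each scene weighted equally)."""
    if not metrics:
        raise ValueError("no scenes to aggregate")
    return Table1Row(
        mean_re=float(np.mean([m.scene_mean_re for m in metrics])),
        mean_nre=float(np.mean([m.scene_mean_nre for m in metrics])),
        mean_ssim=float(np.mean([m.scene_mean_ssim for m in metrics])),
        n_scenes=len(metrics),
    )


def reproduce_reference_benchmark(
    data_dir: str | Path,
    methods: tuple[str, ...] = ("identity", "manual:sh", "manual:mls"),
    start_frames: tuple[int, ...] = (20, 200, 400, 600),
    last_frame: int = 749,
    compute_image_ssim: bool = False,
) -> pd.DataFrame:
    """Run the full benchmark protocol on a deposited video + annotations.

    ``data_dir`` must contain the annotation XML (``*.xml``) and the frame
    source (a ``frames/`` image directory or a video container file). Four
    scenes with start frames 20/200/400/600 are evaluated to frame 749 and
    aggregated per method. Returns a table with one row per method
    (mean_re, mean_nre, mean_ssim, n_scenes).
    """
    data_dir = Path(data_dir)
    xmls = sorted(data_dir.glob("*.xml"))
    if not xmls:
        raise FileNotFoundError(f"no annotation XML found in {data_dir}")
    annotations = read_cvat_xml(xmls[0])
    frames_dir = data_dir / "frames"
    if frames_dir.is_dir():
        frames = read_frames(frames_dir)
    else:
        videos = sorted(p for p in data_dir.iterdir()
                        if p.suffix.lower() in {".mp4", ".avi", ".mkv"})
        if not videos:
            raise FileNotFoundError(f"no frames/ directory or video file in {data_dir}")
        frames = read_frames(videos[0])
    rows = {}
    for method in methods:
        per_scene = [
            run_scene(frames, annotations, method,
                      SceneSpec(sf, last_frame),
                      compute_image_ssim=compute_image_ssim)
            for sf in start_frames
        ]
        row = aggregate_scenes(per_scene)
        rows[method] = {"mean_re": row.mean_re, "mean_nre": row.mean_nre,
                        "mean_ssim": row.mean_ssim, "n_scenes": row.n_scenes}
    return pd.DataFrame(rows).T
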