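"""End-to-end live-augmentation loop.

One frame is saved as the *start frame* during map acquisition; its
preprocessed image, glare mask and keypoints are computed once. Every
subsequent frame then runs: preprocess → detect/match → quality gate →
single homography (+ optional HMA regions) → per-pixel fusion → display
mask → optional physiological-map overlay. Every failure mode degrades to
showing the unmodified current frame — the pipeline never blocks the live
video.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import KeypointSet, detect_describe, match_features, quality_gate
from .fusion import (
    CandidateWarp,
    build_display_mask,
    build_error_image,
    compose_output,
    fuse_candidates,
    validate_region,
)
from .hsi_overlay import PhysioMap, SensorCalibration, render_overlay
from .io_formats import FrameImage, RunConfig
from .preprocess import GlareMask, preprocess_frame
from .transforms import (
    EstimationError,
    estimate_hma,
    estimate_single_homography,
    warp_image,
)

__all__ = ["PipelineState", "FrameDiagnostics", "process_frame", "run_video"]


@dataclass
class PipelineState:
    """Immutable start-frame context reused for every incoming frame."""

    start_frame: FrameImage
    start_mono: np.ndarray
    start_mask: GlareMask
    start_keypoints: KeypointSet
    config: RunConfig
    physio_map: PhysioMap | None = None
    calibration: SensorCalibration | None = None

    @classmethod
    def initialize(
        cls,
        start_frame: FrameImage,
        config: RunConfig | None = None,
        physio_map: PhysioMap | None = None,
        calibration: SensorCalibration | None = None,
    ) -> "PipelineState":
        cfg = config or RunConfig()
        mono, mask = preprocess_frame(
            start_frame, cfg.glare_lower_frac, cfg.glare_upper_frac,
            glare_mode=cfg.glare_mode, box_size=cfg.box_size,
            clahe_tiles=cfg.clahe_tiles, clahe_clip=cfg.clahe_clip,
        )
        kp = detect_describe(mono, mask, detector=cfg.detector,
                             descriptor=cfg.descriptor)
        return cls(start_frame=start_frame, start_mono=mono, start_mask=mask,
                   start_keypoints=kp, config=cfg, physio_map=physio_map,
                   calibration=calibration)


@dataclass
class FrameDiagnostics:
    frame_index: int
    gated: bool
    gate_reason: str
    mean_match_distance: float | None
    n_matches: int
    inlier_ratio: float
    n_regions: int
    n_valid_regions: int
    suppressed_fraction: float
    timings_ms: dict[str, float] = field(default_factory=dict)
    transform: object | None = None  # estimated start->current transform

    def as_row(self) -> dict:
        row = {
            "frame_index": self.frame_index,
            "gated": self.gated,
            "gate_reason": self.gate_reason,
            "mean_match_distance": self.mean_match_distance,
            "n_matches": self.n_matches,
            "inlier_ratio": self.inlier_ratio,
            "n_regions": self.n_regions,
            "n_valid_regions": self.n_valid_regions,
            "suppressed_fraction": self.suppressed_fraction,
        }
        row.update({f"ms_{k}": round(v, 2) for k, v in self.timings_ms.items()})
        return row


def _passthrough(state: PipelineState, current: FrameImage, reason: str,
                 matches_n: int = 0, mean_d: float | None = None,
                 timings: dict | None = None) -> tuple[FrameImage, FrameDiagnostics]:
    diag = FrameDiagnostics(
        frame_index=current.frame_index, gated=True, gate_reason=reason,
        mean_match_distance=mean_d, n_matches=matches_n, inlier_ratio=0.0,
        n_regions=0, n_valid_regions=0, suppressed_fraction=1.0,
        timings_ms=timings or {},
    )
    return current, diag


def process_frame(state: PipelineState, current: FrameImage
                  ) -> tuple[FrameImage, FrameDiagnostics]:
    """Register one frame and compose the safe output image.

    Never raises on registration failure: any gate or estimation failure
    yields the unmodified current frame with diagnostics explaining why.
    """
    cfg = state.config
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    mono, mask = preprocess_frame(
        current, cfg.glare_lower_frac, cfg.glare_upper_frac,
        glare_mode=cfg.glare_mode, box_size=cfg.box_size,
        clahe_tiles=cfg.clahe_tiles, clahe_clip=cfg.clahe_clip,
    )
    timings["preprocess"] = (time.perf_counter() - t0) * 1e3

    t0 = time.perf_counter()
    kp = detect_describe(mono, mask, detector=cfg.detector, descriptor=cfg.descriptor)
    matches = match_features(state.start_keypoints, kp,
                             retain_frac=cfg.match_retain_frac)
    timings["features"] = (time.perf_counter() - t0) * 1e3

    gate = quality_gate(matches, cfg.detector, threshold=cfg.gate_threshold)
    if not gate.passed:
        return _passthrough(state, current, gate.reason, len(matches),
                            matches.mean_distance, timings)

    t0 = time.perf_counter()
    try:
        if cfg.transform == "HMA":
            region_set = estimate_hma(
                matches.src_xy, matches.dst_xy,
                (current.pixels.shape[1], current.pixels.shape[0]),
                threshold=cfg.ransac_threshold, split_ratio=cfg.hma_split_ratio,
                min_region=cfg.hma_min_region, k_min=cfg.hma_k_min,
                k_max=cfg.hma_k_max, k_divisor=cfg.hma_k_divisor,
                seed=cfg.seed, max_trials=cfg.ransac_max_trials,
            )
            sh = region_set.H_global
        else:
            sh = estimate_single_homography(
                matches.src_xy, matches.dst_xy, threshold=cfg.ransac_threshold,
                seed=cfg.seed, max_trials=cfg.ransac_max_trials,
                confidence=cfg.ransac_confidence,
            )
            region_set = None
    except EstimationError as e:
        return _passthrough(state, current, f"estimation failed: {e}",
                            len(matches), matches.mean_distance, timings)
    timings["estimate"] = (time.perf_counter() - t0) * 1e3
    inlier_ratio = len(sh.inlier_indices) / max(len(matches), 1)

    t0 = time.perf_counter()
    image_size = (current.pixels.shape[1], current.pixels.shape[0])
    candidates = [CandidateWarp(
        warp=warp_image(state.start_frame.pixels, sh),
        error_image=np.empty(0), label="SH",
    )]
    n_regions = n_valid = 0
    if region_set is not None:
        n_regions = len(region_set.regions)
        for k, region in enumerate(region_set.regions):
            if validate_region(region, region_set.H_global, image_size,
                               min_area_frac=cfg.region_min_area_frac,
                               max_h_diff=cfg.region_h_diff_max):
                n_valid += 1
                candidates.append(CandidateWarp(
                    warp=warp_image(state.start_frame.pixels, region.H_local),
                    error_image=np.empty(0), label=f"HMA-{k}",
                ))
    for c in candidates:
        c.error_image = build_error_image(c.warp, current,
                                          closing_size=cfg.closing_size)
    fusion = fuse_candidates(candidates)
    suppress = build_display_mask(fusion.combined_error,
                                  threshold_frac=cfg.error_threshold_frac,
                                  median_size=cfg.median_size)
    fusion.display_mask = ~suppress
    timings["fusion"] = (time.perf_counter() - t0) * 1e3

    t0 = time.perf_counter()
    if state.physio_map is not None and state.calibration is not None:
        output = render_overlay(current, sh, state.physio_map, state.calibration,
                                alpha=cfg.overlay_alpha,
                                display_mask=fusion.display_mask)
    else:
        output = compose_output(fusion, current)
    timings["compose"] = (time.perf_counter() - t0) * 1e3

    diag = FrameDiagnostics(
        frame_index=current.frame_index, gated=False, gate_reason="",
        mean_match_distance=matches.mean_distance, n_matches=len(matches),
        inlier_ratio=inlier_ratio, n_regions=n_regions, n_valid_regions=n_valid,
        suppressed_fraction=float(suppress.mean()), timings_ms=timings,
        transform=sh,
    )
    return output, diag


def run_video(
    frames: list[FrameImage],
    config: RunConfig | None = None,
    start_index: int = 0,
    physio_map: PhysioMap | None = None,
    calibration: SensorCalibration | None = None,
) -> tuple[list[FrameImage], pd.DataFrame]:
    """Process an ordered frame sequence against one start frame.

    Returns the output frames (same order and count as the input) and a log
    DataFrame with one row per frame: gate decisions, match statistics,
    inlier ratios and per-stage timings. Unreadable/failed frames pass
    through unmodified and are logged.
    """
    cfg = config or RunConfig()
    by_index = {f.frame_index: f for f in frames}
    if start_index not in by_index:
        raise ValueError(f"start frame {start_index} not in sequence")
    state = PipelineState.initialize(by_index[start_index], cfg,
                                     physio_map=physio_map, calibration=calibration)
    outputs = []
    rows = []
    for f in frames:
        out, diag = process_frame(state, f)
        outputs.append(out)
        rows.append(diag.as_row())
    return outputs, pd.DataFrame(rows)
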