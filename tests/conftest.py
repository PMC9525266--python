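"""Shared fixtures: synthetic textures, scenes and annotation sets."""

from __future__ import annotations

import numpy as np
import pytest

from lapreg.io_formats import AnnotationSet, FrameImage, LandmarkPoint, LandmarkTrack
from lapreg.synthetic import PhantomSpec, generate_phantom_texture, generate_scene


@pytest.fixture(scope="session")
def texture854() -> FrameImage:
    """Full-size richly textured phantom frame (854x480)."""
    return generate_phantom_texture(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A 320x240, 10-frame scene with smooth homography motion."""
    spec = PhantomSpec(seed=11, size=(320, 240), n_frames=10, n_landmarks=16,
                       translation_amp=6.0, rotation_amp=0.015,
                       perspective_amp=1e-5, glare_count=2, glare_radius=8.0,
                       breathing_period=40)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def static_scene():
    """A zero-motion scene: every frame equals the start frame."""
    spec = PhantomSpec(seed=13, size=(320, 240), n_frames=5, n_landmarks=12,
                       translation_amp=0.0, rotation_amp=0.0,
                       perspective_amp=0.0, scale_amp=0.0, glare_count=0)
    return generate_scene(spec)


def make_annotations(
    n_tracks: int = 10,
    n_frames: int = 5,
    image_size: tuple[int, int] = (200, 150),
    motion_px: float = 7.0,
    seed: int = 0,
) -> AnnotationSet:
    """Random annotation set where every landmark moves each frame."""
    rng = np.random.default_rng(seed)
    w, h = image_size
    tracks = []
    for tid in range(n_tracks):
        x = rng.uniform(0.2 * w, 0.8 * w)
        y = rng.uniform(0.2 * h, 0.8 * h)
        pts = {}
        for f in range(n_frames):
            angle = rng.uniform(0, 2 * np.pi)
            pts[f] = LandmarkPoint(
                float(np.clip(x + f * motion_px * np.cos(angle), 0, w - 1)),
                float(np.clip(y + f * motion_px * np.sin(angle), 0, h - 1)),
                visible=True,
            )
        tracks.append(LandmarkTrack(tid, pts))
    return AnnotationSet(tracks=tracks, n_frames=n_frames, image_size=image_size)
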