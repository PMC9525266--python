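"""Synthetic laparoscopy-like scenes with exact ground truth.

Real evaluation data (deposited video plus CVAT landmark annotations) needs
a download; these generators produce statistically similar inputs with
*known* truth so every stage of the pipeline is testable hermetically:

* a band-limited tissue-like texture with dark vessel-like curves and a
  mid-range dominant green channel (features detectable, glare band
  exercised);
* scenes of frames moved by a known smooth homography path, optionally with
  a low-frequency "breathing" deformation, injected glare spots, and a dark
  moving instrument-like occluder;
* landmark tracks (the true mapped positions, hidden under the occluder)
  exportable as CVAT XML;
* sensor-calibration fixtures: a known HSI-to-color homography, noisy
  annotated point pairs, and a smooth synthetic oxygenation map.

Everything is seeded: the same spec yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import AnnotationSet, FrameImage, LandmarkPoint, LandmarkTrack
from .hsi_overlay import PhysioMap, SensorCalibration, calibrate_sensors
from .transforms import HomographyTransform, apply_homography_to_points

__all__ = [
    "PhantomSpec",
    "generate_phantom_texture",
    "generate_scene",
    "generate_calibration_fixture",
    "SyntheticScene",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic scene.

    Defaults emulate the reference recordings: 854x480 frames, 28 evenly
    spaced landmarks, 750-frame scenes (tests use far fewer), smooth
    perspective motion with a breathing period of 90 frames (~3 s at 30
    fps), a few specular glare spots, and an optional instrument occluder.
    """

    seed: int = 7
    size: tuple[int, int] = (854, 480)  # (W, H)
    n_landmarks: int = 28
    n_frames: int = 750
    # motion model: amplitudes of the smooth homography path
    translation_amp: float = 15.0  # px
    rotation_amp: float = 0.02  # radians
    perspective_amp: float = 2e-5
    scale_amp: float = 0.02
    deformation_amp: float = 0.0  # px of local sinusoidal displacement
    breathing_period: int = 90  # frames
    # artifacts
    glare_count: int = 3
    glare_radius: float = 12.0
    occluder: bool = False
    occluder_width: int = 40

    @property
    def width(self) -> int:
        return self.size[0]

    @property
    def height(self) -> int:
        return self.size[1]


@dataclass
class SyntheticScene:
    frames: list[FrameImage]
    annotations: AnnotationSet
    true_transforms: list[HomographyTransform]  # start(frame 0) -> frame t
    glare_masks: list[np.ndarray]  # True where glare was injected
    spec: PhantomSpec = field(default=PhantomSpec())


def generate_phantom_texture(spec: PhantomSpec) -> FrameImage:
    """Band-limited random texture with vessel-like curvilinear structures.

    The green channel dominates and concentrates in the usable intensity
    band (51, 204), so the glare mask keeps most of the tissue area and
    corner detectors find abundant structure.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.size
    fine = ndimage.gaussian_filter(rng.random((h, w)), 2.0)
    coarse = ndimage.gaussian_filter(rng.random((h, w)), 12.0)
    tex = 0.7 * fine + 0.3 * coarse
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)

    # vessel-like dark random-walk strokes
    vessels = np.zeros((h, w))
    n_vessels = max(3, (w * h) // 60000)
    for _ in range(n_vessels):
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(int(2.0 * max(w, h))):
            xi, yi = int(x), int(y)
            if 0 <= xi < w and 0 <= yi < h:
                vessels[yi, xi] = 1.0
            angle += rng.normal(0, 0.15)
            x += np.cos(angle)
            y += np.sin(angle)
            if not (-20 <= x < w + 20 and -20 <= y < h + 20):
                break
    vessels = ndimage.gaussian_filter(vessels, 1.2)
    vessels = vessels / (vessels.max() + 1e-12)

    green = 80.0 + 100.0 * tex - 45.0 * vessels
    red = 0.75 * green + 25.0 * coarse * 255.0 / 8
    blue = 0.45 * green
    rgb = np.stack([red, green, blue], axis=-1)
    return FrameImage(np.clip(np.rint(rgb), 0, 255).astype(np.uint8), 0)


def _motion_homography(spec: PhantomSpec, t: int) -> np.ndarray:
    """Smooth homography path with H_0 = identity."""
    w, h = spec.size
    cx, cy = w / 2.0, h / 2.0
    phase = 2.0 * np.pi * t / spec.breathing_period
    s1, s2 = np.sin(phase), np.sin(0.5 * phase)
    tx = spec.translation_amp * s1
    ty = spec.translation_amp * 0.6 * s2
    theta = spec.rotation_amp * s2
    scale = 1.0 + spec.scale_amp * s1
    px = spec.perspective_amp * s1
    py = spec.perspective_amp * 0.5 * s2
    c, s = np.cos(theta), np.sin(theta)
    # rotate/scale about the image center, then translate, then perspective
    T1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], float)
    R = np.array([[scale * c, -scale * s, 0], [scale * s, scale * c, 0], [0, 0, 1]], float)
    T2 = np.array([[1, 0, cx + tx], [0, 1, cy + ty], [0, 0, 1]], float)
    P = np.array([[1, 0, 0], [0, 1, 0], [px, py, 1]], float)
    H = P @ T2 @ R @ T1
    return H / H[2, 2]


def _deformation(spec: PhantomSpec, t: int, xx: np.ndarray, yy: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Low-frequency sinusoidal displacement (breathing-like), in px."""
    if spec.deformation_amp == 0.0:
        return np.zeros_like(xx), np.zeros_like(yy)
    w, h = spec.size
    phase = 2.0 * np.pi * t / spec.breathing_period
    a = spec.deformation_amp * np.sin(phase)
    dx = a * np.sin(2 * np.pi * yy / h)
    dy = a * 0.7 * np.cos(2 * np.pi * xx / w)
    return dx, dy


def _landmark_grid(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Evenly spaced landmark positions (with jitter) in start-frame coords."""
    w, h = spec.size
    n = spec.n_landmarks
    cols = int(np.ceil(np.sqrt(n * w / h)))
    rows = int(np.ceil(n / cols))
    xs = np.linspace(0.15 * w, 0.85 * w, cols)
    ys = np.linspace(0.15 * h, 0.85 * h, rows)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    return pts + rng.normal(0, 2.0, pts.shape)


def generate_scene(spec: PhantomSpec) -> SyntheticScene:
    """Generate a full synthetic scene with exact ground truth.

    Frame ``t`` is the base texture moved by the known homography ``H_t``
    (plus the optional local deformation), with glare spots of intensity
    >= 230 and, when enabled, a dark sweeping occluder bar (intensity < 51,
    so the glare/dark mask removes it like a real instrument shaft).
    Landmark positions are the true mapped points, marked invisible under
    the occluder or outside the frame. ``true_transforms[t]`` maps start
    (frame 0) coordinates to frame ``t`` coordinates.
    """
    rng = np.random.default_rng(spec.seed + 1)
    base = generate_phantom_texture(spec)
    w, h = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    landmarks0 = _landmark_grid(spec, rng)
    glare_centers = rng.uniform([0, 0], [w, h], size=(spec.glare_count, 2))

    frames: list[FrameImage] = []
    transforms: list[HomographyTransform] = []
    glare_masks: list[np.ndarray] = []
    tracks: dict[int, dict[int, LandmarkPoint]] = {i: {} for i in range(len(landmarks0))}

    for t in range(spec.n_frames):
        H = _motion_homography(spec, t)
        Hi = np.linalg.inv(H)
        flat = np.column_stack([xx.ravel(), yy.ravel()])
        src, _ = apply_homography_to_points(Hi, flat)
        sx = src[:, 0].reshape(h, w)
        sy = src[:, 1].reshape(h, w)
        ddx, ddy = _deformation(spec, t, xx, yy)
        sx = sx - ddx
        sy = sy - ddy
        chans = [
            ndimage.map_coordinates(base.pixels[:, :, c].astype(float),
                                    [sy, sx], order=1, mode="nearest")
            for c in range(3)
        ]
        img = np.stack(chans, axis=-1)

        # glare spots (fixed scene positions, slight per-frame wobble)
        gmask = np.zeros((h, w), bool)
        for gi, (gx0, gy0) in enumerate(glare_centers):
            gx = gx0 + 3.0 * np.sin(2 * np.pi * t / spec.breathing_period + gi)
            gy = gy0 + 2.0 * np.cos(2 * np.pi * t / spec.breathing_period + gi)
            rr = (xx - gx) ** 2 + (yy - gy) ** 2
            spot = rr < spec.glare_radius**2
            gmask |= spot
            img[spot] = np.clip(img[spot] + 200, 240, 255)

        # sweeping dark occluder bar
        occ = np.zeros((h, w), bool)
        if spec.occluder:
            x_pos = (t / max(spec.n_frames - 1, 1)) * (w + 2 * spec.occluder_width) - spec.occluder_width
            occ = np.abs(xx - x_pos) < spec.occluder_width / 2
            img[occ] = 25.0

        frames.append(FrameImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), t))
        transforms.append(HomographyTransform(H))
        glare_masks.append(gmask)

        mapped, _ = apply_homography_to_points(H, landmarks0)
        if spec.deformation_amp:
            # first-order inversion: the rendered source offset d is small
            # and smooth, so the true image position of p is ~ H(p) + d(H(p))
            ldx, ldy = _deformation(spec, t, mapped[:, 0], mapped[:, 1])
            mapped = mapped + np.column_stack([ldx, ldy])
        for i, (mx, my) in enumerate(mapped):
            inside = 0 <= mx <= w - 1 and 0 <= my <= h - 1
            occluded = bool(occ[int(np.clip(my, 0, h - 1)), int(np.clip(mx, 0, w - 1))])
            tracks[i][t] = LandmarkPoint(float(mx), float(my),
                                         visible=inside and not occluded)

    annotation = AnnotationSet(
        tracks=[LandmarkTrack(i, pts) for i, pts in tracks.items()],
        n_frames=spec.n_frames,
        image_size=spec.size,
    )
    return SyntheticScene(frames=frames, annotations=annotation,
                          true_transforms=transforms, glare_masks=glare_masks,
                          spec=spec)


def generate_two_motion_pair(
    seed: int = 23,
    size: tuple[int, int] = (854, 480),
    shift: float = 10.0,
    n_points: int = 150,
) -> tuple[FrameImage, FrameImage, np.ndarray, np.ndarray,
           tuple[np.ndarray, np.ndarray]]:
    """Half-plane phantom pair with two opposing affine (pure-shift) motions.

    The left half of the start frame moves by (+shift, 0) and the right half
    by (−shift, 0) — piecewise motion no single homography can follow, the
    regime the region-based transform targets. The default ±10 px keeps both
    local homographies inside the region-validity envelope around the global
    fit. Returns (start, current, match_src, match_dst, (H_left, H_right));
    the matches are exact point correspondences sampled away from the seam.
    """
    w, h = size
    pad = int(np.ceil(2 * shift)) + 20
    tex = generate_phantom_texture(
        PhantomSpec(seed=seed, size=(w + 2 * pad, h))).pixels
    s = int(round(shift))
    start = FrameImage(np.ascontiguousarray(tex[:, pad : pad + w]), 0)
    cur = np.empty_like(start.pixels)
    # current[:, x] = start[:, x - s] on the left, start[:, x + s] on the right
    cur[:, : w // 2] = tex[:, pad - s : pad + w // 2 - s]
    cur[:, w // 2 :] = tex[:, pad + w // 2 + s : pad + w + s]
    current = FrameImage(cur, 1)

    rng = np.random.default_rng(seed + 1)
    src = rng.uniform([10, 10], [w - 10, h - 10], (n_points, 2))
    margin = 2 * s + 10  # keep correspondences off the ambiguous seam band
    keep = np.abs(src[:, 0] - w / 2) > margin
    src = src[keep]
    left = src[:, 0] < w / 2
    dst = src.copy()
    dst[left, 0] += s
    dst[~left, 0] -= s
    H_left = np.array([[1, 0, float(s)], [0, 1, 0], [0, 0, 1]])
    H_right = np.array([[1, 0, -float(s)], [0, 1, 0], [0, 0, 1]])
    return start, current, src, dst, (H_left, H_right)


def generate_calibration_fixture(
    seed: int = 0,
    n_pairs: int = 25,
    noise_sigma: float = 0.0,
    map_size: tuple[int, int] = (180, 135),  # (W', H') of the HSI grid
    frame_size: tuple[int, int] = (854, 480),
) -> tuple[PhysioMap, HomographyTransform, tuple[np.ndarray, np.ndarray]]:
    """Known sensor calibration with annotated pairs and a synthetic StO2 map.

    Returns (map, true H_cal, (hsi_xy, color_xy)); the color-side points are
    the true mapping of the HSI-side points plus optional Gaussian noise of
    ``noise_sigma`` px, mimicking annotation error.
    """
    rng = np.random.default_rng(seed)
    mw, mh = map_size
    fw, fh = frame_size
    sx = 0.9 * fw / mw
    sy = 0.9 * fh / mh
    H = np.array([
        [sx, 0.03 * sx, 0.04 * fw],
        [-0.02 * sy, sy, 0.03 * fh],
        [1e-5, -8e-6, 1.0],
    ])
    truth = HomographyTransform(H)
    hsi_xy = rng.uniform([2, 2], [mw - 3, mh - 3], size=(n_pairs, 2))
    color_xy = truth.apply(hsi_xy)
    if noise_sigma > 0:
        color_xy = color_xy + rng.normal(0, noise_sigma, color_xy.shape)
    field_vals = ndimage.gaussian_filter(rng.random((mh, mw)), 8.0)
    field_vals = (field_vals - field_vals.min()) / (field_vals.max() - field_vals.min() + 1e-12)
    pmap = PhysioMap(values=0.3 + 0.6 * field_vals)
    return pmap, truth, (hsi_xy, color_xy)
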