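"""Reprojection-error protocol, SSIM, scene evaluation and aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from lapreg.evaluation import (
    RegistrationMetrics,
    SceneSpec,
    aggregate_scenes,
    compute_ssim,
    ground_truth_transform,
    point_errors,
    run_scene,
)
from lapreg.io_formats import AnnotationSet, LandmarkPoint, LandmarkTrack
from lapreg.transforms import HomographyTransform

from conftest import make_annotations


def _two_frame_annotations(p0, p1):
    tracks = [
        LandmarkTrack(i, {0: LandmarkPoint(*a, True), 1: LandmarkPoint(*b, True)})
        for i, (a, b) in enumerate(zip(p0, p1))
    ]
    return AnnotationSet(tracks=tracks, n_frames=2, image_size=(500, 500))


# ---------------------------------------------------------------------------
# point errors


def test_identity_transform_nre_is_one():
    ann = make_annotations(n_tracks=10, n_frames=5, motion_px=7.0, seed=1)
    for f in range(1, 5):
        errs = point_errors(None, ann, 0, f)
        for e in errs:
            assert e.nre == pytest.approx(1.0)
            assert e.re == pytest.approx(e.moved)


def test_perfect_transform_zero_error():
    H = np.array([[1.05, 0.01, 8.0], [0.0, 0.97, -4.0], [0, 0, 1.0]])
    rng = np.random.default_rng(2)
    p0 = rng.uniform(50, 400, (8, 2))
    t = HomographyTransform(H)
    p1 = t.apply(p0)
    ann = _two_frame_annotations(p0, p1)
    for e in point_errors(t, ann, 0, 1):
        assert e.re == pytest.approx(0.0, abs=1e-9)
        assert e.nre == pytest.approx(0.0, abs=1e-9)


def test_nre_is_re_over_moved():
    p0 = [(100.0, 100.0)]
    p1 = [(116.0, 100.0)]  # moved 16 px
    ann = _two_frame_annotations(p0, p1)
    # transform leaves the point 4 px short of the target
    t = HomographyTransform(np.array([[1, 0, 12.0], [0, 1, 0], [0, 0, 1.0]]))
    (e,) = point_errors(t, ann, 0, 1)
    assert e.re == pytest.approx(4.0)
    assert e.moved == pytest.approx(16.0)
    assert e.nre == pytest.approx(0.25)


def test_zero_motion_landmark_excluded_from_nre():
    p0 = [(100.0, 100.0), (200.0, 200.0)]
    p1 = [(100.0, 100.0), (210.0, 200.0)]
    ann = _two_frame_annotations(p0, p1)
    errs = point_errors(None, ann, 0, 1)
    assert errs[0].nre is None  # did not move
    assert errs[1].nre == pytest.approx(1.0)


def test_re_invariant_to_track_relabeling():
    rng = np.random.default_rng(3)
    p0 = rng.uniform(0, 400, (6, 2))
    p1 = p0 + rng.normal(0, 5, p0.shape)
    a = _two_frame_annotations(p0, p1)
    perm = rng.permutation(6)
    b = _two_frame_annotations(p0[perm], p1[perm])
    re_a = sorted(e.re for e in point_errors(None, a, 0, 1))
    re_b = sorted(e.re for e in point_errors(None, b, 0, 1))
    np.testing.assert_allclose(re_a, re_b)


def test_no_covisible_landmarks_empty():
    tracks = [LandmarkTrack(0, {0: LandmarkPoint(1, 1, True),
                                1: LandmarkPoint(1, 1, False)})]
    ann = AnnotationSet(tracks=tracks, n_frames=2, image_size=(10, 10))
    assert point_errors(None, ann, 0, 1) == []


# ---------------------------------------------------------------------------
# SSIM


def test_ssim_identical_images_is_one():
    rng = np.random.default_rng(4)
    img = rng.integers(0, 255, (64, 64), dtype=np.uint8)
    assert compute_ssim(img, img) == pytest.approx(1.0)


def test_ssim_symmetry():
    rng = np.random.default_rng(5)
    a = rng.integers(0, 255, (64, 64), dtype=np.uint8)
    b = rng.integers(0, 255, (64, 64), dtype=np.uint8)
    assert compute_ssim(a, b) == pytest.approx(compute_ssim(b, a), abs=1e-12)


def test_ssim_matches_direct_formula():
    """Independent implementation: explicit Gaussian-window SSIM formula."""
    rng = np.random.default_rng(6)
    a = rng.integers(0, 255, (24, 24)).astype(np.float64)
    b = np.clip(a + rng.normal(0, 20, a.shape), 0, 255).astype(np.uint8).astype(np.float64)

    sigma, truncate = 1.5, 3.5
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k1 = np.exp(-0.5 * x**2 / sigma**2)
    k1 /= k1.sum()
    kern = np.outer(k1, k1)

    def wmean(img):
        return ndimage.correlate(img, kern, mode="reflect")

    ux, uy = wmean(a), wmean(b)
    vx = wmean(a * a) - ux * ux
    vy = wmean(b * b) - uy * uy
    vxy = wmean(a * b) - ux * uy
    R = 255.0
    C1, C2 = (0.01 * R) ** 2, (0.03 * R) ** 2
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / ((ux**2 + uy**2 + C1) * (vx + vy + C2))
    expected = S[r:-r, r:-r].mean()
    assert compute_ssim(a.astype(np.uint8), b.astype(np.uint8)) == pytest.approx(
        expected, abs=1e-9)


def test_ssim_shape_mismatch_raises():
    with pytest.raises(ValueError):
        compute_ssim(np.zeros((8, 8), np.uint8), np.zeros((9, 8), np.uint8))


# ---------------------------------------------------------------------------
# scenes


def test_static_scene_exact_method_zero_error(static_scene):
    scene = static_scene
    spec = SceneSpec(0, scene.spec.n_frames - 1)

    def true_method(start, current):
        return scene.true_transforms[current.frame_index]

    m = run_scene(scene.frames, scene.annotations, true_method, spec,
                  compute_image_ssim=False)
    assert m.scene_mean_re == pytest.approx(0.0, abs=1e-9)


def test_manual_sh_on_known_homography_scene(small_scene):
    scene = small_scene
    spec = SceneSpec(0, scene.spec.n_frames - 1)
    m = run_scene(scene.frames, scene.annotations, "manual:sh", spec,
                  compute_image_ssim=False)
    assert m.scene_mean_re < 0.5


def test_method_failure_recorded_as_identity_and_flagged(static_scene):
    from lapreg.transforms import EstimationError

    scene = static_scene

    def failing(start, current):
        raise EstimationError("synthetic failure")

    m = run_scene(scene.frames, scene.annotations, failing,
                  SceneSpec(0, scene.spec.n_frames - 1), compute_image_ssim=False)
    assert m.per_frame["flagged"].all()
    # static scene: identity is perfect, so RE is 0 even for the fallback
    assert m.scene_mean_re == pytest.approx(0.0, abs=1e-9)


def test_scene_aggregation_passthrough_and_mean():
    import pandas as pd

    df = pd.DataFrame({"frame_index": [1], "mean_re": [2.0], "mean_nre": [0.5],
                       "ssim": [0.9], "n_points": [5], "flagged": [False]})
    m = RegistrationMetrics(df, 2.0, 0.5, 0.9, 0)
    one = aggregate_scenes([m])
    assert (one.mean_re, one.mean_nre, one.mean_ssim) == (2.0, 0.5, 0.9)
    four = aggregate_scenes([m] * 4)
    assert four.mean_re == pytest.approx(2.0)
    m2 = RegistrationMetrics(df, 4.0, 0.7, 0.8, 0)
    two = aggregate_scenes([m, m2])
    assert two.mean_re == pytest.approx(3.0)
    assert two.mean_nre == pytest.approx(0.6)


def test_scene_frame_order_invariance(small_scene):
    scene = small_scene
    spec = SceneSpec(0, scene.spec.n_frames - 1)
    m1 = run_scene(scene.frames, scene.annotations, "identity", spec,
                   compute_image_ssim=False)
    m2 = run_scene(list(reversed(scene.frames)), scene.annotations, "identity",
                   spec, compute_image_ssim=False)
    assert m1.scene_mean_re == pytest.approx(m2.scene_mean_re)


def test_identity_scene_mean_nre_is_exactly_one(small_scene):
    scene = small_scene
    m = run_scene(scene.frames, scene.annotations, "identity",
                  SceneSpec(0, scene.spec.n_frames - 1), compute_image_ssim=False)
    assert m.scene_mean_nre == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ground-truth transforms


def test_ground_truth_sh_recovers_exact_homography(small_scene):
    scene = small_scene
    t = ground_truth_transform(scene.annotations, 0, 5, mode="SH")
    truth = scene.true_transforms[5]
    corners = np.array([[0, 0], [319, 0], [0, 239], [319, 239]], float)
    np.testing.assert_allclose(t.apply(corners), truth.apply(corners), atol=0.01)


def test_ground_truth_mls_mode_runs(small_scene):
    scene = small_scene
    field = ground_truth_transform(scene.annotations, 0, 3, mode="MLS")
    errs = point_errors(field, scene.annotations, 0, 3)
    # control points interpolate their own targets closely
    assert np.mean([e.re for e in errs]) < 0.5


def test_ground_truth_insufficient_points_raise():
    from lapreg.transforms import EstimationError

    tracks = [LandmarkTrack(i, {0: LandmarkPoint(i * 10, 5, True),
                                1: LandmarkPoint(i * 10 + 1, 5, True)})
              for i in range(3)]
    ann = AnnotationSet(tracks=tracks, n_frames=2, image_size=(50, 10))
    with pytest.raises(EstimationError):
        ground_truth_transform(ann, 0, 1, mode="SH")


def test_landmark_jitter_recovery():
    """Manual-annotation SH stays within a few sigma of truth under jitter."""
    from lapreg.synthetic import PhantomSpec, generate_scene

    spec = PhantomSpec(seed=31, size=(320, 240), n_frames=100, n_landmarks=20,
                       translation_amp=6.0, rotation_amp=0.01, glare_count=0,
                       breathing_period=50)
    scene = generate_scene(spec)
    rng = np.random.default_rng(99)
    sigma = 0.5
    for track in scene.annotations.tracks:
        for f, p in track.points.items():
            track.points[f] = LandmarkPoint(p.x + rng.normal(0, sigma),
                                            p.y + rng.normal(0, sigma), p.visible)
    m = run_scene(scene.frames, scene.annotations, "manual:sh",
                  SceneSpec(0, 99), compute_image_ssim=False)
    assert m.scene_mean_re < 3 * sigma
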