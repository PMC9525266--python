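"""Geometric transformation estimation and application.

Three transformation models map the saved start frame onto the current
frame:

* **SH** — a single 3x3 homography, robustly estimated with RANSAC
  (reprojection threshold 5 px) and refit by normalized DLT least squares
  on the inlier set. Appropriate for near-planar scenes and camera motion.
* **HMA** — hierarchical multi-affine: matches are clustered by position
  and displacement, each cluster gets its own RANSAC homography, clusters
  with poor inlier support are bisected and re-fit, and accepted regions
  absorb nearby unassigned matches. Captures piecewise motion (e.g. organ
  vs. background).
* **MLS** — affine moving-least-squares deformation: every vertex of a
  uniform grid receives its own weighted affine fit to the control points
  (weights 1/|p_i - v|^(2*alpha)), and pixels between vertices are
  bilinearly interpolated. Captures smooth non-rigid tissue deformation.

Conventions: points are (x=column, y=row) row-vectors; homographies act on
column vectors [x, y, 1]^T and are normalized so H[2,2] = 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform
from sklearn.cluster import KMeans

__all__ = [
    "HomographyTransform",
    "RegionTransform",
    "RegionTransformSet",
    "DeformationField",
    "WarpResult",
    "EstimationError",
    "estimate_single_homography",
    "estimate_hma",
    "estimate_mls_field",
    "apply_homography_to_points",
    "apply_field_to_points",
    "warp_image",
    "transform_to_json",
    "transform_from_json",
]


class EstimationError(RuntimeError):
    """Transformation could not be estimated (too few points / degenerate)."""


@dataclass
class HomographyTransform:
    """A 3x3 projective transform with its RANSAC inlier bookkeeping."""

    H: np.ndarray  # (3, 3), H[2, 2] == 1
    inlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    reproj_threshold: float = 5.0

    def __post_init__(self) -> None:
        H = np.asarray(self.H, float)
        if H.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(H[2, 2]) < 1e-12:
            raise ValueError("cannot normalize homography with H[2,2] ~ 0")
        self.H = H / H[2, 2]
        if abs(np.linalg.det(self.H)) < 1e-12:
            raise ValueError("homography is singular")

    @classmethod
    def identity(cls) -> "HomographyTransform":
        return cls(np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        mapped, _ = apply_homography_to_points(self.H, points)
        return mapped

    def inverse(self) -> "HomographyTransform":
        return HomographyTransform(np.linalg.inv(self.H),
                                   reproj_threshold=self.reproj_threshold)

    def compose(self, other: "HomographyTransform") -> "HomographyTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return HomographyTransform(self.H @ other.H)


@dataclass
class RegionTransform:
    """One HMA region: a local homography with its spatial support."""

    polygon: np.ndarray  # convex hull vertices in current-frame coords, (K, 2)
    H_local: HomographyTransform
    member_indices: np.ndarray  # indices into the MatchSet

    @property
    def area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class RegionTransformSet:
    regions: list[RegionTransform]
    H_global: HomographyTransform


@dataclass
class DeformationField:
    """Affine-MLS displacement of a uniform grid, interpolated bilinearly."""

    spacing: float
    grid_shape: tuple[int, int]  # (ny, nx)
    vertices: np.ndarray  # (ny, nx, 2) lattice positions
    displaced: np.ndarray  # (ny, nx, 2) mapped positions
    alpha: float
    control_src: np.ndarray  # (n, 2)
    control_dst: np.ndarray  # (n, 2)
    image_size: tuple[int, int]  # (W, H)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_field_to_points(self, points)


@dataclass
class WarpResult:
    """An image resampled into current-frame geometry plus source validity."""

    image: np.ndarray  # uint8, same rank as input
    validity: np.ndarray  # (H, W) bool, True where the source pixel existed


# ---------------------------------------------------------------------------
# homography


def apply_homography_to_points(H: np.ndarray, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map (N, 2) points through H with perspective divide.

    Returns (mapped, valid); a point whose homogeneous w vanishes (maps to
    the plane at infinity) is flagged invalid and set to NaN.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    hom = np.column_stack([pts, np.ones(len(pts))])
    q = hom @ np.asarray(H, float).T
    w = q[:, 2]
    valid = np.abs(w) > 1e-12
    out = np.full((len(pts), 2), np.nan)
    out[valid] = q[valid, :2] / w[valid, None]
    return out, valid


def _transfer_errors(H: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    mapped, valid = apply_homography_to_points(H, src)
    err = np.full(len(src), np.inf)
    err[valid] = np.linalg.norm(mapped[valid] - dst[valid], axis=1)
    return err


def _dlt_fit(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT least-squares homography over all given pairs."""
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:
        raise EstimationError("degenerate point configuration for DLT fit")
    H = tf.params
    if abs(H[2, 2]) < 1e-12 or not np.all(np.isfinite(H)):
        raise EstimationError("DLT fit produced an invalid homography")
    return H / H[2, 2]


def estimate_single_homography(
    src: np.ndarray,
    dst: np.ndarray,
    threshold: float = 5.0,
    seed: int = 17,
    max_trials: int = 2000,
    confidence: float = 0.995,
) -> HomographyTransform:
    """RANSAC homography (inlier: transfer error < threshold) + DLT refit.

    The returned transform's inlier set is re-evaluated under the refit
    matrix, so every recorded inlier satisfies the threshold.
    """
    src = np.asarray(src, float).reshape(-1, 2)
    dst = np.asarray(dst, float).reshape(-1, 2)
    if len(src) != len(dst):
        raise ValueError("src/dst length mismatch")
    if len(src) < 4:
        raise EstimationError(f"need >= 4 point pairs, got {len(src)}")
    if len(src) == 4:
        H = _dlt_fit(src, dst)
        inl = np.nonzero(_transfer_errors(H, src, dst) < threshold)[0]
        return HomographyTransform(H, inlier_indices=inl, reproj_threshold=threshold)
    with warnings.catch_warnings():
        # a degenerate configuration surfaces below as EstimationError
        warnings.filterwarnings("ignore", message="No inliers found")
        model, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=threshold,
            max_trials=max_trials,
            stop_probability=confidence,
            rng=seed,
        )
    if model is None or inliers is None or inliers.sum() < 4:
        raise EstimationError("RANSAC failed to find a homography")
    H = _dlt_fit(src[inliers], dst[inliers])
    inl = np.nonzero(_transfer_errors(H, src, dst) < threshold)[0]
    if len(inl) < 4:
        inl = np.nonzero(inliers)[0]
    return HomographyTransform(H, inlier_indices=inl, reproj_threshold=threshold)


# ---------------------------------------------------------------------------
# hierarchical multi-affine (HMA)


def _convex_hull(points: np.ndarray) -> np.ndarray | None:
    if len(points) < 3:
        return None
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    return points[hull.vertices]


def estimate_hma(
    src: np.ndarray,
    dst: np.ndarray,
    image_size: tuple[int, int],
    threshold: float = 5.0,
    split_ratio: float = 0.5,
    min_region: int = 4,
    k_min: int = 2,
    k_max: int = 10,
    k_divisor: int = 50,
    merge_ratio: float = 0.8,
    seed: int = 17,
    max_trials: int = 2000,
) -> RegionTransformSet:
    """Hierarchical multi-affine region estimation.

    Matches are k-means clustered on (position, displacement) with
    k = clamp(N / k_divisor, k_min, k_max); each cluster is fit with RANSAC,
    clusters whose inlier ratio falls below ``split_ratio`` are bisected on
    position and re-fit, accepted clusters absorb unassigned matches whose
    transfer error under the cluster homography is below ``threshold``,
    clusters whose union is explained by one joint homography (inlier
    fraction >= ``merge_ratio``) are merged, and clusters retaining fewer
    than ``min_region`` inliers are discarded. The global homography over
    all matches is always estimated and returned.
    """
    src = np.asarray(src, float).reshape(-1, 2)
    dst = np.asarray(dst, float).reshape(-1, 2)
    n = len(src)
    H_global = estimate_single_homography(src, dst, threshold=threshold, seed=seed,
                                          max_trials=max_trials)
    k = int(np.clip(round(n / k_divisor), k_min, k_max))
    k = min(k, max(n // min_region, 1))
    feats = np.column_stack([dst, dst - src])
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(feats)

    queue: list[np.ndarray] = [np.nonzero(labels == c)[0] for c in range(k)]
    accepted: list[tuple[np.ndarray, HomographyTransform]] = []
    budget = 4 * k  # bound the divide-and-refit recursion
    while queue and budget > 0:
        budget -= 1
        members = queue.pop()
        if len(members) < min_region:
            continue
        try:
            Hl = estimate_single_homography(src[members], dst[members],
                                            threshold=threshold, seed=seed,
                                            max_trials=max_trials)
        except EstimationError:
            continue
        ratio = len(Hl.inlier_indices) / len(members)
        if ratio < split_ratio and len(members) >= 2 * min_region:
            sub = KMeans(n_clusters=2, n_init=5, random_state=seed).fit_predict(dst[members])
            a, b = members[sub == 0], members[sub == 1]
            if len(a) and len(b):
                queue.extend([a, b])
                continue
        inlier_members = members[Hl.inlier_indices]
        if len(inlier_members) >= min_region:
            accepted.append((inlier_members, Hl))

    # expansion: each unassigned match may be absorbed by the region whose
    # homography explains it best, if within the threshold
    assigned = np.zeros(n, bool)
    for members, _ in accepted:
        assigned[members] = True
    unassigned = np.nonzero(~assigned)[0]
    if len(unassigned) and accepted:
        errs = np.stack([_transfer_errors(Hl.H, src[unassigned], dst[unassigned])
                         for _, Hl in accepted])
        best = errs.argmin(axis=0)
        best_err = errs[best, np.arange(len(unassigned))]
        absorb = best_err < threshold
        grown: list[tuple[np.ndarray, HomographyTransform]] = []
        for r, (members, Hl) in enumerate(accepted):
            extra = unassigned[absorb & (best == r)]
            members = np.sort(np.concatenate([members, extra]))
            if len(extra) >= 1 and len(members) >= 4:
                try:  # re-fit on the grown membership
                    Hl = estimate_single_homography(src[members], dst[members],
                                                    threshold=threshold, seed=seed,
                                                    max_trials=max_trials)
                    members = members[Hl.inlier_indices]
                except EstimationError:
                    pass
            grown.append((np.sort(members), Hl))
        accepted = grown

    # merge clusters that one joint homography explains (e.g. a single
    # global motion fragmented by the initial k-means)
    changed = True
    while changed and len(accepted) > 1:
        changed = False
        for i in range(len(accepted)):
            for j in range(i + 1, len(accepted)):
                union = np.union1d(accepted[i][0], accepted[j][0])
                try:
                    Hu = estimate_single_homography(
                        src[union], dst[union], threshold=threshold,
                        seed=seed, max_trials=max_trials)
                except EstimationError:
                    continue
                if len(Hu.inlier_indices) >= merge_ratio * len(union):
                    rest = [accepted[r] for r in range(len(accepted))
                            if r not in (i, j)]
                    accepted = rest + [(union[Hu.inlier_indices], Hu)]
                    changed = True
                    break
            if changed:
                break

    regions = []
    for members, Hl in accepted:
        if len(members) < min_region:
            continue
        hull = _convex_hull(dst[members])
        if hull is None:
            continue
        regions.append(RegionTransform(polygon=hull, H_local=Hl,
                                       member_indices=members))
    return RegionTransformSet(regions=regions, H_global=H_global)


# ---------------------------------------------------------------------------
# moving least squares


def _mls_displace(
    query: np.ndarray, p: np.ndarray, q: np.ndarray, alpha: float
) -> np.ndarray:
    """Affine-MLS image f(v) for query points v (vectorized over v).

    f(v) = (v - p*) M + q*  with  M = (sum w_i p̂_i^T p̂_i)^-1 sum w_j p̂_j^T q̂_j,
    w_i = 1 / |p_i - v|^(2 alpha); a query within 1e-9 of a control point
    snaps to that point's target exactly.
    """
    v = np.atleast_2d(query).astype(float)
    diff = v[:, None, :] - p[None, :, :]  # (m, n, 2)
    d2 = (diff**2).sum(-1)
    snap = d2 < 1e-18
    d2_safe = np.where(snap, 1.0, d2)
    w = 1.0 / d2_safe**alpha
    w = np.where(snap, 0.0, w)
    wsum = w.sum(1)
    # rows with a snapped control point are overwritten below
    wsum = np.where(wsum == 0, 1.0, wsum)
    pstar = (w @ p) / wsum[:, None]
    qstar = (w @ q) / wsum[:, None]
    ph = p[None, :, :] - pstar[:, None, :]
    qh = q[None, :, :] - qstar[:, None, :]
    A = np.einsum("mn,mni,mnj->mij", w, ph, ph)
    B = np.einsum("mn,mni,mnj->mij", w, ph, qh)
    snap_any = snap.any(1)
    A[snap_any] = np.eye(2)  # these rows are overwritten by the snap rule
    B[snap_any] = np.eye(2)
    try:
        M = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as e:
        raise EstimationError("collinear control points: singular MLS system") from e
    out = np.einsum("mi,mij->mj", v - pstar, M) + qstar
    snap_rows, snap_cols = np.nonzero(snap)
    out[snap_rows] = q[snap_cols]
    return out


def estimate_mls_field(
    control_src: np.ndarray,
    control_dst: np.ndarray,
    image_size: tuple[int, int],
    grid_density: float = 0.2,
    alpha: float = 1.0,
) -> DeformationField:
    """Affine moving-least-squares deformation on a uniform grid.

    ``grid_density`` 0.2 places lattice vertices every round(1/0.2) = 5 px;
    the lattice covers the full image (last row/column may lie just past the
    border). Control points must contain at least 3 non-collinear positions.
    """
    p = np.asarray(control_src, float).reshape(-1, 2)
    q = np.asarray(control_dst, float).reshape(-1, 2)
    if len(p) != len(q):
        raise ValueError("control point count mismatch")
    if len(p) < 3:
        raise EstimationError("need >= 3 control points")
    centered = p - p.mean(0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise EstimationError("collinear control points")
    if grid_density <= 0 or grid_density > 1:
        raise ValueError("grid_density must be in (0, 1]")
    spacing = max(round(1.0 / grid_density), 1)
    W, H = image_size
    gx = np.arange(0, W - 1 + spacing, spacing, dtype=float)
    gy = np.arange(0, H - 1 + spacing, spacing, dtype=float)
    vx, vy = np.meshgrid(gx, gy)
    vertices = np.stack([vx, vy], axis=-1)
    displaced = _mls_displace(vertices.reshape(-1, 2), p, q, alpha).reshape(vertices.shape)
    return DeformationField(
        spacing=float(spacing), grid_shape=vertices.shape[:2],
        vertices=vertices, displaced=displaced, alpha=alpha,
        control_src=p, control_dst=q, image_size=(W, H),
    )


def apply_field_to_points(field: DeformationField, points: np.ndarray) -> np.ndarray:
    """Evaluate the deformation at arbitrary points by bilinear interpolation.

    Points outside the lattice are clamped to the border cell.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    s = field.spacing
    ny, nx = field.grid_shape
    fx = np.clip(pts[:, 0] / s, 0, nx - 1)
    fy = np.clip(pts[:, 1] / s, 0, ny - 1)
    x0 = np.minimum(fx.astype(int), nx - 2) if nx > 1 else np.zeros(len(pts), int)
    y0 = np.minimum(fy.astype(int), ny - 2) if ny > 1 else np.zeros(len(pts), int)
    tx = (fx - x0) if nx > 1 else np.zeros(len(pts))
    ty = (fy - y0) if ny > 1 else np.zeros(len(pts))
    x1 = np.minimum(x0 + 1, nx - 1)
    y1 = np.minimum(y0 + 1, ny - 1)
    d = field.displaced
    out = (
        d[y0, x0] * ((1 - tx) * (1 - ty))[:, None]
        + d[y0, x1] * (tx * (1 - ty))[:, None]
        + d[y1, x0] * ((1 - tx) * ty)[:, None]
        + d[y1, x1] * (tx * ty)[:, None]
    )
    return out


# ---------------------------------------------------------------------------
# warping


def _sample(image: np.ndarray, src_x: np.ndarray, src_y: np.ndarray) -> np.ndarray:
    """Bilinear backward sampling (edge-clamped; validity handled by caller)."""
    coords = [src_y, src_x]
    if image.ndim == 2:
        return ndimage.map_coordinates(image.astype(np.float64), coords, order=1,
                                       mode="nearest")
    chans = [
        ndimage.map_coordinates(image[:, :, c].astype(np.float64), coords, order=1,
                                mode="nearest")
        for c in range(image.shape[2])
    ]
    return np.stack(chans, axis=-1)


def warp_image(image: np.ndarray, transform,
               output_shape: tuple[int, int] | None = None) -> WarpResult:
    """Backward-warp an image into current-frame geometry.

    ``transform`` maps start-frame coordinates to current-frame coordinates
    (a :class:`HomographyTransform` or :class:`DeformationField`); warping
    inverts it per output pixel and samples the source bilinearly. The
    validity mask is True where the inverse map lands inside the source.
    For a deformation field the backward map is itself an affine-MLS field
    built from the swapped control points. ``output_shape`` is (H, W) of the
    target canvas, defaulting to the source shape.
    """
    sh, sw = image.shape[:2]
    h, w = output_shape if output_shape is not None else (sh, sw)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    if isinstance(transform, HomographyTransform):
        src, valid_w = apply_homography_to_points(np.linalg.inv(transform.H), flat)
        src = np.where(valid_w[:, None], src, -1.0)
    elif isinstance(transform, DeformationField):
        back = estimate_mls_field(
            transform.control_dst, transform.control_src,
            transform.image_size, grid_density=1.0 / transform.spacing,
            alpha=transform.alpha,
        )
        src = apply_field_to_points(back, flat)
    else:
        raise TypeError(f"cannot warp with {type(transform).__name__}")
    sx = src[:, 0].reshape(h, w)
    sy = src[:, 1].reshape(h, w)
    eps = 1e-6  # tolerate float fuzz at the exact border
    validity = (sx >= -eps) & (sx <= sw - 1 + eps) & (sy >= -eps) & (sy <= sh - 1 + eps)
    warped = _sample(image, sx, sy)
    warped = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    warped[~validity] = 0
    return WarpResult(image=warped, validity=validity)


# ---------------------------------------------------------------------------
# serialization


def transform_to_json(transform) -> str:
    if isinstance(transform, HomographyTransform):
        return json.dumps({"type": "homography", "H": transform.H.tolist()})
    if isinstance(transform, DeformationField):
        return json.dumps({
            "type": "mls",
            "spacing": transform.spacing,
            "alpha": transform.alpha,
            "image_size": list(transform.image_size),
            "control_src": transform.control_src.tolist(),
            "control_dst": transform.control_dst.tolist(),
        })
    raise TypeError(f"cannot serialize {type(transform).__name__}")


def transform_from_json(text: str):
    obj = json.loads(text)
    if obj["type"] == "homography":
        return HomographyTransform(np.array(obj["H"]))
    if obj["type"] == "mls":
        return estimate_mls_field(
            np.array(obj["control_src"]), np.array(obj["control_dst"]),
            tuple(obj["image_size"]), grid_density=1.0 / obj["spacing"],
            alpha=obj["alpha"],
        )
    raise ValueError(f"unknown transform type {obj['type']!r}")
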