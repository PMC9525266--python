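# Methods

This note documents the models, parameter choices and numerical decisions
behind `lapreg`, and what the synthetic test fixtures do and do not show
about real surgical video.

## Registration model

The scene is treated as approximately planar with small parallax: a saved
start frame is related to each later frame by a projective transform, with
local deviations caused by breathing, instrument manipulation and tissue
deformation. Three estimators of increasing flexibility are provided.

**Single homography (SH).** RANSAC over the matched keypoints with an
inlier threshold of 5 px transfer error, at most 2000 trials, stop
probability 0.995, and a fixed default seed (17) so runs are bit-for-bit
reproducible. The consensus set is refit by normalized DLT (Hartley
RMS-√2 normalization, SVD least squares), the inlier set is re-evaluated
under the refit matrix, and the matrix is normalized to H[2,2] = 1 — the
fusion stage differences raw matrix entries, so a fixed gauge is mandatory.

**Hierarchical multi-affine (HMA).** Matches are k-means clustered on
(position, displacement) with k = clamp(N/50, 2, 10). Each cluster is fit
with the SH estimator; clusters with inlier ratio < 0.5 are bisected by
k-means on position and re-fit; accepted clusters absorb unassigned matches
whose transfer error under the cluster homography is < 5 px and are then
re-fit; clusters whose union is explained by one joint homography (inlier
fraction ≥ 0.8) are merged, so a single global motion yields a single
region; clusters with fewer than 4 inliers are discarded. Each region
carries the convex hull of its member keypoints in current-frame
coordinates as spatial support. These hyperparameters are this package's
own: phantom-recovery tests pin the *behavior* (a two-motion scene yields
two regions that recover their generators), not the constants.

**Moving least squares (MLS).** Affine MLS on a uniform grid: for grid
vertex v, weights wᵢ = 1/|pᵢ − v|^(2α) with α = 1, weighted centroids p*,
q*, M = (Σ wᵢ p̂ᵢᵀ p̂ᵢ)⁻¹ Σ wⱼ p̂ⱼᵀ q̂ⱼ, and f(v) = (v − p*)M + q*. A vertex
within 10⁻⁹ px of a control point snaps to that point's target. A "grid
density of 20 %" is read as a lattice spacing of round(1/0.2) = 5 px;
pixels between vertices are bilinearly interpolated. When all control pairs
satisfy one global affine, every displaced vertex equals the affine image
exactly (the tests assert this to 10⁻⁶ px). Warping by a field solves the
backward map by building a second MLS field from the swapped control
points; this is exact for affine motion and a standard first-order
approximation otherwise.

Warping is backward with bilinear sampling (edge-clamped); a validity mask
records which output pixels had a source inside the image, with a 10⁻⁶ px
tolerance at the exact border so float fuzz cannot flip validity.

## Preprocessing

Features are detected on the green channel — the best-contrasted channel
for tissue — after a normalized 5×5 box filter (replicate borders, so the
global mean is preserved to ±1 intensity level) and CLAHE with an 8×8 tile
grid and clip limit 2.0 on the conventional per-bin scale (each 256-bin
histogram bin limited to twice the uniform count; converted internally to
the normalized clip limit of the scikit-image implementation, 2/256).

The glare mask removes intensity extremes: a pixel is kept iff
51 < v < 204, i.e. strictly inside 20–80 % of the 8-bit maximum value
range (a `percentile` mode computing thresholds from the image's own
distribution is available behind a config switch). The kept area is eroded
with a 5×5 elliptical structuring element; pixels outside the image count
as unusable, so the mask also shrinks at the frame border — features are
never detected on unreliable border pixels. The mask is computed on the
*raw* green channel, not the equalized one, so the band refers to the
original photometry.

## Matching and the quality gate

Descriptors are matched by exhaustive Hamming distance with crosscheck
(mutual nearest neighbors); matches are sorted ascending by distance with
ties broken on the index pair for determinism, and the best
ceil(0.20 · n) are retained — crosscheck first, then the 20 % selection,
and ceil keeps at least one match. The pipeline halts (and shows the live
frame) when the retained mean distance strictly exceeds the detector's
threshold: 35 for ORB1000, 55 for A-KAZE, 65 for BRISK. These thresholds
are calibrated so that a passing set corresponds to a RANSAC inlier ratio
of about 0.6 at the 5 px threshold; a mean exactly at the threshold passes.

This build registers one detector backend, ORB at a 1000-keypoint cap
(scikit-image implementation; detection oversamples 2×, keypoints outside
the glare mask are dropped, and the strongest 1000 by corner response are
kept). The A-KAZE/BRISK/BEBLID configuration names are part of the
interface but raise a clear error, and detector-specific benchmark rows
are reported, never asserted — they depend on the detector implementation.

## Fusion and the display mask

The start frame is warped by SH and by each *valid* HMA region — valid iff
its support polygon covers more than 2 % of the image area and the
entrywise sum |H_local − H_SH| is below 50 (both normalized to
H[2,2] = 1; the rule suppresses regions far from the global motion, and
with it near-degenerate local fits). Each candidate's error image is the
absolute difference of green channels against the current frame, forced to
255 where the warp has no source, then closed with a 35×35 elliptical
structuring element (replicate border) so selection is spatially coherent.
Error images are computed on raw green channels rather than equalized ones
— CLAHE is local and would distort photometric error (config switch
available). The candidate with the lowest error wins each pixel; ties go
to the first candidate in list order, SH first, as the globally trusted
model.

The combined minimum-error image drives the display mask: suppress where
error > 10 % of the range (on 8-bit data: > 25.5, i.e. ≥ 26 — the boundary
is pinned by a test), then clean with a 35×35 majority-vote median. The
median is implemented with an exact integral-image counter (replicate
border) rather than a float smoothing filter, so the brute-force oracle
comparison in the tests is exact and no threshold wobble can occur. All
failure modes degrade to showing the unmodified live frame; the pipeline
never blocks the video.

## Evaluation protocol

A scene is a start frame registered against every later frame. Per frame,
each landmark visible in both frames contributes RE = |T(p_start) −
p_current|₂ and nRE = RE / |p_start − p_current|₂. Landmarks that moved
less than 10⁻⁶ px contribute to RE but are excluded from the nRE mean
(their normalization is undefined; an epsilon-floor mode exists for
comparison runs). Frame means weight landmarks equally, scene means weight
frames equally, overall means weight scenes equally. SSIM (Gaussian 11×11
window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, range 255, population covariance)
is computed on grayscale between the current frame and the warped start
frame, with out-of-validity pixels filled by the current frame's mean
intensity (fill mode configurable). Quality gating and display-mask
postprocessing are deliberately bypassed during evaluation: the metrics
measure the raw estimators. Frames where a method fails are recorded with
the identity transform and flagged. "Manual-annotation" reference methods
fit SH or MLS directly to the ground-truth landmark pairs.

## Synthetic fixtures

The generators emulate the statistical structure the pipeline assumes, not
photorealism: band-limited texture with dark vessel-like random-walk
strokes and a mid-range dominant green channel (> 80 % of green mass
inside the usable band, ≥ 500 ORB keypoints at full size); smooth
homography motion (sinusoidal translation/rotation/scale/perspective with
a 90-frame breathing period, H₀ = identity); optional low-frequency
sinusoidal local deformation; glare spots injected at ≥ 240 intensity;
an instrument-like dark occluder bar (< 51 intensity, so the same mask
that removes glare removes it, as with real instrument shafts). Landmark
tracks are the true mapped positions, hidden under the occluder, and
round-trip through CVAT XML. Defaults mirror the reference recordings:
854×480 frames, 28 landmarks, 750-frame scenes; tests use 320×240 scenes
of 5–100 frames and 50-frame full-size scenes sampled every 5th frame for
the recovery checks — enough frames to cover a full breathing period while
keeping the default suite fast. Under deformation, landmark truth uses the
first-order inversion x ≈ H(p) + d(H(p)) of the rendered backward offset,
accurate to O(|d|·∇d) for the small smooth fields generated.

The two-motion fusion fixture shifts the half-planes by ±10 px. Larger
opposing motions (e.g. ±20 px) are exercised in the transform tests, but
lie outside the design envelope of the region-validity rule: with motions
that far apart, the global RANSAC fit can legitimately converge to a
"blend" homography from which one region differs by more than the 50-sum
rule, and the rule then (correctly, by its own logic) suppresses that
region. ±10 px represents local deformation around a dominant motion — the
regime the region validity check was designed for.

What passing these tests does *not* show: robustness to real specular
dynamics, motion blur, smoke, wet reflective instruments, compression
artifacts, or textureless organ surfaces. The deposited annotated scene
(see README) is the only realistic check; its reproduction test runs
whenever that data is present.

## Sensor calibration and overlay

The HSI→color mapping is a single homography fitted by least squares to
*all* annotated pairs — annotations are trusted, so no RANSAC — with the
RMS residual reported as an annotation-quality figure (with σ = 1 px
annotation noise and 25 pairs, the RMS residual stays within [0.5σ, 2σ];
tested over 100 seeds). The physiological map is clipped to [0, 1],
rendered with a perceptually ordered colormap (viridis; any documented
perceptual map is acceptable and the choice is recorded in the map
object), NaN values transparent, and composited as
round(α·color + (1−α)·gray) with α = 0.5 by default ("semitransparent").
Overlay pixels outside the warped map, with invalid map data, or
suppressed by the display mask show the untouched live frame. Differences
in sensor resolution are absorbed entirely by the calibration homography;
there is no separate resampling step.

## Numerical and interface decisions

- Coordinates are 0-based, x = column, y = row; CVAT points are consumed
  verbatim (CVAT is already 0-based). Start-frame indices 20/200/400/600
  are treated as 0-based sequence indices, with a `frame_index_base`
  config flag for 1-based comparison runs.
- The CVAT reader treats a point as invisible when either the `outside` or
  the `occluded` attribute is set — exports differ in which they use.
- Video decoding is codec-dependent; the canonical, bit-exact test input
  is a PNG sequence. Containers are delegated to imageio.
- RANSAC inlier comparisons are strict (< threshold); the quality gate is
  strictly-greater; the error-mask threshold is strictly-greater than
  25.5. All three boundaries are pinned by tests.
- `run_scene` accepts a `frame_step` for subsampled smoke evaluations; the
  acceptance-level phantom recovery uses step 5 on 50-frame scenes and 5
  generator seeds.

## Known limitations

- Only the ORB detector backend is registered; BEBLID descriptors and the
  A-KAZE/BRISK detectors are interface stubs.
- MLS fusion candidates are an extension hook; the pinned combination is
  SH + HMA.
- The backward MLS warp is a first-order inverse (exact only for affine
  fields).
- Timing is logged per stage but never asserted — it is hardware-dependent
  and no real-time guarantee is implied.
- No deep-learning homography estimation, no 3-D reconstruction, no camera
  calibration, no spectral reconstruction of oxygenation from raw
  hyperspectral cubes.
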