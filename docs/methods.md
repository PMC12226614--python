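# Methods

This note documents the models, the synthetic stand-in data, the numerical
choices, and the known limitations of `cleftrecon`.

## Camera model and pose estimation

The projection is a pinhole camera with a similarity pose applied to world
points: X_c = s·R·X_w + T, then (u, v) = (f_x X_c/Z_c + c_x, f_y Y_c/Z_c +
c_y). Image coordinates are 0-based with the origin at the top-left corner,
u rightward, v downward, and pixel centers at integer coordinates.
Intrinsics are approximated, not calibrated: principal point at the image
center and f_x = f_y = (width/2)/tan(fov/2) with a default 53° horizontal
field of view (a typical smartphone main camera). Lens distortion and
rolling shutter are not modelled.

Pose estimation from ≥ 4 sparse 2D–3D correspondences is damped nonlinear
least squares (Levenberg–Marquardt via `scipy.optimize.least_squares`) over
a minimal 7-parameter encoding: axis-angle rotation, translation (mm), and
log-scale. Residuals are reprojection errors in pixels, optionally
√weight-scaled; a soft barrier on the camera-frame depth keeps iterates in
front of the camera. The default initialization places the point-cloud
centroid on the optical axis at 4× its bounding radius with identity
rotation and unit scale, which guarantees positive depth at the first
evaluation. If the fit from the given initialization stays above 1 px RMS,
additional starts from eight canonical rotations (identity, 90°/180° about
each axis) are tried and the best kept — the palate's canonical "mirror
view" is a 180° rotation away from the identity, so a single-start solver
would routinely land in the wrong basin.

**Scale/depth gauge.** With a fixed approximate K, the projection is
exactly invariant under (s, T) → (ks, kT). Scale and depth are therefore
identified only up to this one-parameter family; all contracts are stated
on reprojections (and, for fitting, on the recovered shape), not on the raw
pose parameters. Returned poses are normalized to s = 1.

## PCA shape model

Training meshes in template correspondence are pre-aligned by generalized
Procrustes analysis — rigid-only by default; scale normalization is a flag,
kept off because palate size is a clinically meaningful shape feature the
model should retain. The aligned 3V-vectors are centered and decomposed by
thin SVD; mode variances use the sample convention s²/(n−1). The retained
mode count is the smallest k whose cumulative variance fraction reaches the
threshold (default 0.999). No prior is imposed at build time; regularization
enters only in fitting.

Encoding a mesh (`project_to_model`) is a pure orthogonal projection onto
the mode basis; callers evaluating raw meshes against a model must first
bring them into the model frame (`align_to_model`, rigid Kabsch onto the
mean shape) because training meshes were aligned internally.
`reconstruction_error` does this by default.

Identity duplicates (several meshes of one patient at different ages) are
treated as independent samples.

## Synthetic palate family

The generator replaces patient intraoral scans. A palate is a height field
on a fixed n×n grid (default 100×100 = 10000 vertices, so all generated
meshes are in correspondence by construction):

- a smooth dome of configurable width/length/height
  (defaults 34 × 38 × 10 mm, infant-scale);
- a horseshoe ridge field: two lateral Gaussian bands merging into an
  anterior arc (ridge height 4 mm, band width 4 mm). The template's contact
  region is the vertex set where this canonical field exceeds 0.5 (~30% of
  vertices), standing in for the plate contact area on the alveolar ridges;
- a cleft: a smooth gap of configurable width at a signed lateral offset,
  cutting through the anterior half — vertices are pushed laterally away
  from the cleft line and depressed, both proportionally to the cleft
  width, so the family interpolates continuously down to a cleft-free
  palate;
- smooth seeded noise (bicubically upsampled 6×6 Gaussian grid, amplitude
  0.3 mm) for per-identity variation.

Family sampling draws dome dimensions from Gaussians around the defaults,
cleft width uniform in 2–12 mm and laterality uniform in ±6 mm. Vertex
colors are a mucosa-like pink with ridge lightening and seeded mottling.

The renderer is a deterministic z-buffered software rasterizer with flat
Lambertian shading (ambient 0.15 by default), a smooth noise background,
and optional linear motion blur. Camera augmentation perturbs a canonical
mirror view by ±20° per axis and ±15% distance; blur is drawn in 0–2 px.
Landmark annotations are exact projections of the landmark-subset vertices;
occluded landmarks are kept at their projected coordinates and flagged by a
z-buffer visibility bit (training uses them by default, maskable by flag).

What the generator does **not** emulate: photorealistic wet-tissue
materials, specularities, texture detail, saliva, instruments/fingers in
frame, real lighting, camera noise or rolling shutter. Passing tests on
this family demonstrates correctness of the geometry/learning machinery and
qualitative scaling behaviour, not clinical performance on photographs —
the synthetic-to-real domain gap is explicitly out of scope.

## Landmark sub-sampling

The 10000 template vertices are sub-sampled to 1000 landmarks by weighted
farthest-point sampling on graph hop distances over the template
connectivity (no coordinates needed, so the topology type stays geometry
free). The selection score is weight × distance with weight `ridge_weight`
(default 4) inside the contact region, yielding a proportionally denser
sample where the plate touches. Deterministic for a given seed; output
sorted and unique.

## Landmark predictor

A channels-last numpy implementation: strided 3×3 convolution encoder
(default widths 8-16-32-64, each halving resolution), a 256-unit dense
layer, and a 3L-dimensional head — 2L landmark means plus L per-landmark
variances shared between u and v (softplus + 1e-6 floor for positivity).
Coordinates are normalized to [−1, 1] inside the network and de-normalized
(and rescaled to the original image size) at the interface; variances are
reported in px². Training is Adam (lr 1e-3, batch 16) on the mean
per-coordinate Gaussian NLL, with early stopping on validation NLL
(patience 10) and best-weights restore — the operationalization of "train
until convergence". Everything is seeded; two runs with the same seed
produce identical losses.

Augmentation (all seeded): rotation about the image center with the
analytic coordinate transform applied to landmarks, horizontal flips (with
an optional left/right landmark symmetry permutation), per-channel color
shifts, and additive Gaussian noise whose level is drawn per sample in
[0, noise_std]. The per-sample level matters: a constant noise level gives
the network no image-quality axis to learn, and the predicted variance then
fails to track input degradation. With a wide quality axis (noise_std ≈
0.4 at toy scale) the variance head calibrates: corrupted inputs receive
larger σ², and an all-noise image larger still. This is aleatoric
calibration along a trained axis — Gaussian-NLL training gives no general
out-of-distribution guarantee.

## Flip-flop fitting

Alternates until both sub-steps' parameter updates fall below tolerance
(default 1e-6 relative) in the same outer iteration, or 100 outer
iterations:

- **pose step** — `estimate_pose` against the currently reconstructed
  shape, warm-started from the previous pose (multi-start only in the first
  iteration);
- **shape step** — one damped Gauss–Newton update of the eigenmode weights
  with the full jacobian of the perspective division, co-updating the
  pose's log-scale and depth t_z in the same linear solve, with a Tikhonov
  prior λ·Σ w_k²/var_k (default λ = 1e-3) and backtracking line search on
  the true cost.

Two numerical points discovered in implementation and worth recording.
First, linearizing only the numerator of the projection (freezing depths)
is *not* a descent direction along size-like eigenmodes; backtracking then
stalls at ~1 mm surface error on exact landmarks. The full Gauss–Newton
jacobian fixes this. Second, global scale and object depth are nearly
exchangeable with size-like eigenmodes under a fixed approximate K; a pure
pose/shape alternation zigzags along this valley with a linear rate near
0.95. Solving scale and depth jointly with the weights removes the valley
from the alternation; the concept-verification error then lands at ~0.01–
0.2 mm per seed. Convergence steps are measured on gauge-normalized pose
parameters so motion along the projectively invisible (s, T) → (ks, kT)
family does not prevent termination.

Per-landmark weights multiply user emphasis (`point_weights`, e.g. a ridge
patch) and, when enabled, inverse predicted variances. σ²-weighting is off
by default: predicted confidences exist, but whether they should enter the
fit is left to the user.

## Dense video annotation

From one sparsely annotated frame, landmarks propagate by patch matching:
the template patch (21×21 px) is anchored at the *annotated* frame — the
long-term-tracking formulation — and located by normalized
cross-correlation inside a ±20 px window that follows the track, with
parabolic sub-pixel refinement (skipped at near-perfect matches, where
asymmetric texture biases the parabola vertex). Tracks whose peak
correlation drops below 0.6 are flagged lost, never fabricated. Frame-to-
frame matching was tried first and rejected: it accumulates ~0.3 px drift
per frame. Any external long-term tracker can be plugged in through the
same call contract.

Per frame, a pose is estimated from the ≥ 4 surviving tracks (previous
frame's pose as init) and all template vertices are reprojected, giving
dense annotations (10000 per frame on the default template). Quality
filtering accepts a frame iff the in-bounds fraction is ≥ 90%, the sparse
reprojection RMSE ≤ 3 px, and the pose jump ≤ 0.1 — where the jump metric
is the Frobenius distance of Frobenius-normalized 3×4 projection matrices.
Normalizing by the matrix norm (rather than the focal length) makes the
metric dimensionless and invariant to the scale gauge; with focal
normalization the mm-scale translation entries dominate and sub-degree
camera motion already trips the threshold. Non-rigid template-to-scan
registration is consumed as an upstream input, not implemented.

## Evaluation and extrapolation

Surface errors are correspondence-based per-vertex Euclidean distances
(mm), optionally restricted to a region; landmark errors are RMSE in
normalized image units (coordinates divided by half the image size).

The model-size experiment holds out 20% of the family, builds models on
seeded subsets of increasing size at 99.9% retained variance, and reports
the median held-out reconstruction error over 5 replicates. The
dataset-size experiment trains a predictor per identity count on seeded
renders and evaluates landmark RMSE and post-fit surface error on renders
of held-out identities. Whether the original scaling analysis evaluated on
held-out or training meshes is not documented anywhere we could find;
held-out is the default, a flag selects training-set evaluation.

Learning curves are summarized by y(n) = a·e^(−bn) + c with a, b > 0,
fitted by multi-start trust-region least squares (decay-rate starts spread
over 10⁻³–5); the asymptote c is the extrapolated convergence point. A fit
whose decay rate pins at the search bound (e.g. for increasing curves) is
flagged as model misfit rather than silently reported.

**Problem sizes.** The test suite and acceptance script run at desk scale,
chosen so the full suite completes in minutes on one CPU: 30–50-mesh
families on 30×30 to 100×100 grids, 64×64 renders, 50–200 landmarks, 24–100
images per identity, identity counts 1–8 with 3 replicates. The
concept-verification procedure runs at the full default template scale
(10000 vertices, 1000 landmarks, 50 training meshes, 10 fit seeds).

## Limitations

- No real-image validation: the domain gap between the rasterized synthetic
  family and clinical photographs is not addressed here, and numbers
  obtained on synthetic data do not transfer.
- The fixed-K scale/depth gauge means absolute size is not observable from
  a single uncalibrated image; recovered shape is reliable, metric pose is
  not.
- The renderer's Lambertian model omits specular wet tissue, the dominant
  appearance feature of real intraoral images.
- Uncertainty estimates are aleatoric and calibrated only along axes
  represented in training; they are not an out-of-distribution detector.
- The flip-flop fitter's shape prior (λ = 1e-3) mildly shrinks
  out-of-distribution shapes toward the mean; set λ = 0 for the
  unregularized fit.
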