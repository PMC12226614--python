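# cleftrecon

Single-image 3D intraoral reconstruction for cleft palate geometry.

Infants born with a cleft lip and palate are commonly treated presurgically
with an orthodontic plate that must fit the individual palate precisely.
Obtaining the required patient-specific 3D model today takes an intraoral
scanner or a manual impression — expensive, licensed, or risky equipment
that is hard to access in low-resource settings. `cleftrecon` implements a
smartphone-compatible alternative: predict dense 2D landmarks on a single
photograph of the palate (taken via a dental mirror), then fit a statistical
shape model to those landmarks to recover the 3D surface. It is aimed at
researchers in medical image analysis and statistical shape modelling who
want a complete, reproducible, CPU-scale implementation of this pipeline.

Because clinical scans and videos cannot be shipped, the package includes a
first-class synthetic data module: parametric palate meshes (dome, alveolar
ridges, variable cleft gap) in template correspondence by construction, and
a deterministic software renderer producing images with exact per-vertex
landmark annotations.

## The model

**Projection.** A palate point X_w ∈ R³ (mm) maps to image coordinates
(u, v) through a pinhole camera,

    z_c [u, v, 1]^T = K [R | T] (s · X_w, 1)^T ,
    K = [[f_x, 0, c_x], [0, f_y, c_y], [0, 0, 1]] ,

with a similarity pose (rotation R, translation T, a single global scale s)
and normalization by the camera-frame depth z_c. K is approximated from the
image size and a default 53° horizontal field of view.

**Shape model.** Template-corresponded training meshes (V vertices) are
rigidly aligned by generalized Procrustes analysis, stacked as 3V-vectors
and decomposed by PCA: a shape is x = x̄ + Bᵀw, with orthonormal eigenmode
rows B and weights w. The retained mode count is the smallest k capturing
≥ 99.9% of the training variance.

**Landmark prediction.** A small convolutional network regresses, for each
of 1000 sub-sampled template vertices (sampled more densely on the ridge
contact regions), the mean (u, v) of a Gaussian over its image position and
a per-landmark variance σ², trained with the negative Gaussian
log-likelihood per coordinate

    L = ½ [ log max(σ², eps) + (y − μ)² / max(σ², eps) ] ,

which penalizes both error and wrong predictions made with high confidence.

**Fitting.** Reconstruction alternates ("flip-flop") between the similarity
pose (nonlinear least squares over R, T, s) and the eigenmode weights
(damped Gauss–Newton at fixed pose), until both converge in the same outer
iteration. Any landmark subset can be emphasized — e.g. the ridge contact
area the treatment plate touches — and predicted variances can optionally
enter as inverse-variance weights.

The package also implements the surrounding experimental machinery: dense
video annotation (patch tracking from one sparsely annotated frame, dense
reprojection, quality filtering), model-size and dataset-size scaling
experiments, and exponential learning-curve extrapolation
y(n) = a·e^(−bn) + c whose asymptote c estimates the convergence point.

## Worked example

```python
import numpy as np
from cleftrecon import (approximate_intrinsics, build_pca, fit_flip_flop,
                        project, reconstruct, sample_coefficients, synthetic_family)
from cleftrecon.evaluation import surface_error
from cleftrecon.synthetic_data import random_pose

# 1. a seeded family of corresponded synthetic cleft palates
topology, meshes, params = synthetic_family(40, seed=0, nx=40, ny=40, n_landmarks=200)

# 2. PCA shape model truncated at 99.9% cumulative variance
model = build_pca(meshes, variance_threshold=0.999, topology=topology)
print(f"model: {model.n_training} meshes -> {model.n_modes} modes")

# 3. concept check: project an in-distribution shape, fit it back from 2D alone
cam = approximate_intrinsics(256, 256)      # smartphone-like camera, 53 deg fov
truth = reconstruct(model, sample_coefficients(model, 123))
pose = random_pose(truth, cam, np.random.default_rng(5))
landmarks = project(truth.vertices[topology.landmark_subset], pose, cam)

result = fit_flip_flop(landmarks, model, cam)
fitted = reconstruct(model, result.coeffs)
err = surface_error(fitted, truth, region=topology.contact_region)
print(f"fit: reprojection RMSE {result.residual_rmse:.4f} px")
print(f"contact-region surface error: mean {err.mean:.4f} mm, max {err.max:.4f} mm")
```

Output:

```
model: 40 meshes -> 30 modes
fit: reprojection RMSE 0.0129 px
contact-region surface error: mean 0.0436 mm, max 0.0856 mm
```

The fitter recovers the 3D surface from its noise-free 2D projections to
hundredths of a millimetre over the plate contact region — far inside the
0.5 mm mean error that plate manufacturing considers clinically precise.
The residual quantifies the information lost by dropping the depth
dimension (plus the remaining pose/scale ambiguity of a fixed, approximate
K).

A command-line interface exposes the full pipeline
(`cleftrecon generate | build-model | train | predict | annotate | fit |
reconstruct | evaluate | fixtures`); run `cleftrecon --help`.

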