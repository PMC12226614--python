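"""Alternating ("flip-flop") pose/shape fitting of the PCA model to 2D landmarks.

The fitter alternates two sub-problems until both converge in the same outer
iteration: (a) a pose step, nonlinear least squares over rotation,
translation and global scale against the currently reconstructed shape, and
(b) a shape step, a damped Gauss-Newton update of the eigenmode weights at
fixed pose (the projection is linear in the shape for fixed pose up to the
per-landmark depth normalization; the full jacobian of the perspective
division is re-linearized every outer iteration). An
optional Tikhonov prior lambda * sum(w_k^2 / variance_k) regularizes the
shape step, and per-landmark weights may combine a user-supplied emphasis map
(for example the ridge contact region) with inverse predicted variances.

The shape step is accepted only if it lowers the true reprojection cost
(backtracked otherwise), so the weighted cost is non-increasing across outer
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core_geometry import (
    CameraIntrinsics,
    CorrespondenceSet,
    Landmarks2D,
    SimilarityPose,
    TriMesh,
    estimate_pose,
)
from .exceptions import (
    ConvergenceError,
    InsufficientCorrespondencesError,
    InvalidParameterError,
    TopologyError,
)
from .shape_model import ShapeCoefficients, ShapeModel, reconstruct

__all__ = ["FitConfig", "FitResult", "fit_flip_flop", "reconstruct_from_image"]


@dataclass
class FitConfig:
    """Tolerances, weighting and initialization of the flip-flop fitter."""

    pose_tol: float = 1e-6
    shape_tol: float = 1e-6
    max_outer_iters: int = 100
    point_weights: Optional[np.ndarray] = None
    use_sigma_weighting: bool = False
    shape_prior_lambda: float = 1e-3
    init_pose: Optional[SimilarityPose] = None
    init_coeffs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.pose_tol <= 0 or self.shape_tol <= 0:
            raise InvalidParameterError("tolerances must be positive")
        if self.shape_prior_lambda < 0:
            raise InvalidParameterError("shape_prior_lambda must be >= 0")


@dataclass
class FitResult:
    """Recovered pose, shape coefficients and reprojection residuals."""

    pose: SimilarityPose
    coeffs: ShapeCoefficients
    residual_rmse: float
    per_landmark_residuals: np.ndarray
    outer_iters: int
    converged: bool
    cost_history: List[float] = field(default_factory=list)


def _gauge_normalize(pose: SimilarityPose) -> SimilarityPose:
    """Fix the scale/translation gauge: (s, T) -> (1, T/s).

    The pinhole projection is exactly invariant under (s, T) -> (ks, kT), so
    scale and translation are only identified up to this one-parameter family
    when K is fixed. Normalizing to s = 1 after every outer iteration keeps
    the parameters bounded and makes step-size convergence tests meaningful;
    reprojections (and the recovered shape) are unchanged.
    """
    if pose.scale == 1.0:
        return pose
    return SimilarityPose(pose.rotation, pose.translation / pose.scale, 1.0)


def _project_uv(points: np.ndarray, pose: SimilarityPose, cam: CameraIntrinsics):
    xc = pose.apply(points)
    z = np.maximum(xc[:, 2], 1e-9)
    u = cam.fx * xc[:, 0] / z + cam.cx
    v = cam.fy * xc[:, 1] / z + cam.cy
    return np.column_stack([u, v]), z


def fit_flip_flop(
    landmarks: Landmarks2D,
    model: ShapeModel,
    cam: CameraIntrinsics,
    cfg: FitConfig = None,
) -> FitResult:
    """Fit the shape model to 2D landmarks over the template landmark subset.

    ``landmarks`` must contain one point per entry of the model topology's
    ``landmark_subset`` (in subset order). Terminates when both the pose and
    the shape parameter updates fall below their tolerances in the same outer
    iteration, or at ``max_outer_iters``.
    """
    if cfg is None:
        cfg = FitConfig()
    subset = model.topology.landmark_subset
    if subset.size == 0:
        raise TopologyError("model topology has no landmark subset")
    if len(landmarks) != len(subset):
        raise TopologyError(
            f"expected {len(subset)} landmarks (the template subset), got {len(landmarks)}"
        )

    L = len(subset)
    k = model.n_modes
    target = landmarks.points

    w = np.ones(L) if cfg.point_weights is None else np.asarray(cfg.point_weights, float).copy()
    if len(w) != L or np.any(w < 0):
        raise InvalidParameterError("point_weights must be L non-negative values")
    if cfg.use_sigma_weighting and landmarks.sigma2 is not None:
        w = w / landmarks.sigma2
    usable = w > 0
    if usable.sum() < 4:
        raise InsufficientCorrespondencesError("need >= 4 landmarks with positive weight")
    w = w / w[usable].mean()  # conditioning only; relative weights preserved

    mean_sub = model.mean_vertices[subset]                       # (L, 3)
    basis_sub = model.components.reshape(k, -1, 3)[:, subset, :] if k else np.zeros((0, L, 3))

    def shape_points(weights: np.ndarray) -> np.ndarray:
        if k == 0:
            return mean_sub
        return mean_sub + np.tensordot(weights, basis_sub, axes=1)

    def cost_of(pose: SimilarityPose, weights: np.ndarray) -> float:
        uv, _ = _project_uv(shape_points(weights), pose, cam)
        r2 = np.sum((uv - target) ** 2, axis=1)
        c = float(np.sum(w[usable] * r2[usable]))
        if cfg.shape_prior_lambda > 0 and k:
            c += cfg.shape_prior_lambda * float(np.sum(weights ** 2 / model.variances))
        return c

    coeffs = (
        np.zeros(k)
        if cfg.init_coeffs is None
        else np.asarray(cfg.init_coeffs, dtype=np.float64).copy()
    )
    if len(coeffs) != k:
        raise InvalidParameterError("init_coeffs length mismatch")

    sub_ids = np.arange(L)[usable]
    corr = CorrespondenceSet(sub_ids, target[usable])
    pose = cfg.init_pose
    if pose is None:
        pose = estimate_pose(corr, shape_points(coeffs)[usable], cam, weights=w[usable])

    cost_history = [cost_of(pose, coeffs)]
    converged = False
    outer = 0
    for outer in range(1, cfg.max_outer_iters + 1):
        # (a) pose step against the current reconstructed shape
        prev_params = _gauge_normalize(pose).as_params()
        pose = estimate_pose(
            corr, shape_points(coeffs)[usable], cam,
            init=pose, weights=w[usable], multistart=outer == 1,
        )
        # step size measured on gauge-normalized parameters: motion along the
        # projectively invisible (s, T) -> (ks, kT) family does not count
        new_params = _gauge_normalize(pose).as_params()
        pose_step = np.linalg.norm(new_params - prev_params) / (np.linalg.norm(prev_params) + 1.0)

        # (b) shape step: damped Gauss-Newton over the eigenmode weights,
        # jointly with the pose's log-scale and depth. Global scale and the
        # object depth are nearly exchangeable with size-like eigenmodes
        # under an approximate fixed K (the documented scale/depth
        # ambiguity); co-updating them in the shape solve removes that
        # near-collinear valley from the alternation, which otherwise
        # zigzags along it with a slow linear rate.
        shape_step = 0.0
        if k:
            pts = shape_points(coeffs)
            xc = pose.apply(pts)
            uv, z = _project_uv(pts, pose, cam)
            # camera-frame directions of the modes: s * R @ B
            pb = pose.scale * np.einsum("ij,klj->kli", pose.rotation, basis_sub)  # (k, L, 3)
            # columns for d(log s) and d(tz): dXc/dlogs = Xc - T, dXc/dtz = e_z
            dxs = xc - pose.translation
            cols3 = np.concatenate([pb, dxs[None]], axis=0)      # (k+1, L, 3)
            # jacobian of the perspective division:
            # du/dp = (fx X' - (u - cx) Z') / Z (and likewise for v)
            a = np.empty((2 * L, k + 2))
            a[0::2, : k + 1] = ((cam.fx * cols3[:, :, 0] - (uv[:, 0] - cam.cx) * cols3[:, :, 2]) / z).T
            a[1::2, : k + 1] = ((cam.fy * cols3[:, :, 1] - (uv[:, 1] - cam.cy) * cols3[:, :, 2]) / z).T
            a[0::2, k + 1] = -(uv[:, 0] - cam.cx) / z
            a[1::2, k + 1] = -(uv[:, 1] - cam.cy) / z
            resid = target - uv
            b = np.empty(2 * L)
            b[0::2] = resid[:, 0]
            b[1::2] = resid[:, 1]
            ww = np.repeat(w, 2)
            mask2 = np.repeat(usable, 2)
            aw = a[mask2] * ww[mask2, None]
            ata = a[mask2].T @ aw
            atb = aw.T @ b[mask2]
            if cfg.shape_prior_lambda > 0:
                prior_diag = np.concatenate([1.0 / model.variances, [0.0, 0.0]])
                ata = ata + cfg.shape_prior_lambda * np.diag(prior_diag)
                atb = atb - cfg.shape_prior_lambda * prior_diag * np.concatenate([coeffs, [0.0, 0.0]])
            ata[np.diag_indices_from(ata)] += 1e-12 * max(np.trace(ata), 1.0)
            try:
                delta = np.linalg.solve(ata, atb)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(ata, atb, rcond=None)[0]

            def apply_step(alpha: float):
                trial_w = coeffs + alpha * delta[:k]
                trial_pose = SimilarityPose(
                    pose.rotation,
                    pose.translation + np.array([0.0, 0.0, alpha * delta[k + 1]]),
                    pose.scale * float(np.exp(np.clip(alpha * delta[k], -5, 5))),
                )
                return trial_pose, trial_w

            # backtracking line search on the true cost
            base_cost = cost_of(pose, coeffs)
            new_pose, new_coeffs = pose, coeffs
            alpha = 1.0
            for _ in range(25):
                trial_pose, trial_w = apply_step(alpha)
                if (trial_pose.apply(shape_points(trial_w))[:, 2].min() > 1e-6
                        and cost_of(trial_pose, trial_w) <= base_cost + 1e-12):
                    new_pose, new_coeffs = trial_pose, trial_w
                    break
                alpha *= 0.5
            shape_step = float(
                np.linalg.norm(new_coeffs - coeffs) / (np.linalg.norm(coeffs) + 1.0)
            )
            coeffs = new_coeffs
            pose = new_pose

        cost = cost_of(pose, coeffs)
        if not np.isfinite(cost):
            raise ConvergenceError("flip-flop cost became non-finite")
        cost_history.append(cost)
        if pose_step < cfg.pose_tol and shape_step < cfg.shape_tol:
            converged = True
            break

    uv, _ = _project_uv(shape_points(coeffs), pose, cam)
    per_lm = np.linalg.norm(uv - target, axis=1)
    rmse = float(np.sqrt(np.mean(per_lm[usable] ** 2)))
    return FitResult(
        pose=_gauge_normalize(pose),
        coeffs=ShapeCoefficients(coeffs),
        residual_rmse=rmse,
        per_landmark_residuals=per_lm,
        outer_iters=outer,
        converged=converged,
        cost_history=cost_history,
    )


def reconstruct_from_image(
    image: np.ndarray,
    predictor,
    model: ShapeModel,
    cam: CameraIntrinsics,
    cfg: FitConfig = None,
):
    """The full single-image pipeline: predict landmarks, fit, reconstruct.

    Returns the reconstructed mesh and the :class:`FitResult`. Pass
    ``landmarks`` from any source with the predictor set to None via
    :func:`fit_flip_flop` directly; this wrapper simply composes the stages.
    """
    landmarks = predictor.predict(image)
    if len(landmarks) != len(model.topology.landmark_subset):
        raise TopologyError(
            "predictor landmark count does not match the model landmark subset"
        )
    result = fit_flip_flop(landmarks, model, cam, cfg)
    mesh = reconstruct(model, result.coeffs)
    return mesh, result
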