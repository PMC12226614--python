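"""Error metrics, model-size / dataset-size scaling and learning-curve extrapolation.

The scaling experiments reproduce, on synthetic families, the two analyses
that matter for this pipeline: how the PCA reconstruction error falls as more
meshes enter the model (at a fixed 99.9% retained-variance truncation), and
how landmark prediction and surface reconstruction improve with the number of
training identities. Curves are summarized by a three-parameter exponential

    y(n) = a * exp(-b * n) + c,     a, b > 0

whose asymptote ``c`` is reported as the convergence point: the error level
the method would approach with unbounded data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core_geometry import TriMesh, approximate_intrinsics
from .exceptions import InsufficientDataError, InvalidParameterError, TopologyError
from .shape_model import ErrorSummary, ShapeModel, build_pca, reconstruction_error

__all__ = [
    "ScalingCurve",
    "ExponentialFit",
    "surface_error",
    "model_size_experiment",
    "dataset_size_experiment",
    "fit_exponential",
    "save_curve_csv",
]


@dataclass
class ScalingCurve:
    """Error as a function of sample count, with per-size replicates."""

    sizes: np.ndarray
    errors: np.ndarray                       # median across replicates
    replicate_errors: List[np.ndarray]
    metric: str = "error"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.errors = np.asarray(self.errors, dtype=np.float64)
        if len(self.sizes) != len(self.errors):
            raise InvalidParameterError("sizes/errors length mismatch")
        if np.any(np.diff(self.sizes) <= 0):
            raise InvalidParameterError("sizes must be strictly increasing")
        if np.any(self.errors < 0):
            raise InvalidParameterError("errors must be non-negative")


@dataclass
class ExponentialFit:
    """y(n) = a exp(-b n) + c with the asymptote c as the convergence point."""

    a: float
    b: float
    c: float
    residual_sse: float
    model_misfit: bool = False

    def predict(self, n) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(n, dtype=np.float64)) + self.c


def surface_error(
    fitted: TriMesh, reference: TriMesh, region: Optional[np.ndarray] = None
) -> ErrorSummary:
    """Correspondence-based per-vertex Euclidean distance between two meshes (mm)."""
    if fitted.n_vertices != reference.n_vertices:
        raise TopologyError("meshes must share the template topology")
    d = np.linalg.norm(fitted.vertices - reference.vertices, axis=1)
    if region is not None:
        region = np.asarray(region, dtype=np.int64)
        if region.size == 0:
            raise InvalidParameterError("region must be non-empty")
        d = d[region]
    return ErrorSummary(float(d.mean()), float(d.max()), d)


def model_size_experiment(
    mesh_family: Sequence[TriMesh],
    sizes: Sequence[int],
    variance_threshold: float = 0.999,
    n_heldout: Optional[int] = None,
    n_replicates: int = 5,
    seed: int = 0,
    region: Optional[np.ndarray] = None,
    evaluate_on_heldout: bool = True,
) -> ScalingCurve:
    """PCA reconstruction error versus the number of training meshes.

    For each size and replicate, a seeded subset builds the model (truncated
    at the requested cumulative variance) and the mean reconstruction error is
    measured on held-out meshes (20% of the family by default). The achieved
    retained-variance fractions are recorded in ``extra['retained_variance']``.
    """
    sizes = sorted(int(s) for s in sizes)
    n_total = len(mesh_family)
    if n_heldout is None:
        n_heldout = max(1, int(round(0.2 * n_total)))
    if sizes[-1] + n_heldout > n_total:
        raise InsufficientDataError(
            f"family of {n_total} cannot support size {sizes[-1]} plus {n_heldout} held out"
        )
    rng = np.random.default_rng(seed)
    replicate_errors: List[np.ndarray] = []
    retained: List[List[float]] = []
    for size in sizes:
        errs, fracs = [], []
        for _ in range(n_replicates):
            perm = rng.permutation(n_total)
            held = perm[:n_heldout]
            train = perm[n_heldout : n_heldout + size]
            model = build_pca([mesh_family[i] for i in train], variance_threshold)
            total_var = _total_variance([mesh_family[i] for i in train])
            fracs.append(float(model.variances.sum() / total_var) if total_var > 0 else 1.0)
            eval_idx = held if evaluate_on_heldout else train
            e = [
                reconstruction_error(model, mesh_family[i], region=region).mean
                for i in eval_idx
            ]
            errs.append(float(np.mean(e)))
        replicate_errors.append(np.array(errs))
        retained.append(fracs)
    medians = np.array([np.median(e) for e in replicate_errors])
    return ScalingCurve(
        np.array(sizes), medians, replicate_errors, metric="mean reconstruction error (mm)",
        extra={"retained_variance": retained, "variance_threshold": variance_threshold},
    )


def _total_variance(meshes: Sequence[TriMesh]) -> float:
    from .shape_model import generalized_procrustes

    verts = generalized_procrustes([m.vertices for m in meshes])
    x = np.stack([v.reshape(-1) for v in verts])
    xc = x - x.mean(axis=0)
    return float((xc ** 2).sum() / (len(x) - 1))


def dataset_size_experiment(
    identity_counts: Sequence[int],
    images_per_mesh: int = 24,
    image_size: int = 64,
    n_landmarks: int = 50,
    grid: Tuple[int, int] = (24, 24),
    n_eval_identities: int = 3,
    renders_per_eval: int = 4,
    epochs: int = 30,
    n_replicates: int = 1,
    seed: int = 0,
    fit_surface: bool = True,
) -> Tuple[ScalingCurve, Optional[ScalingCurve]]:
    """Landmark and surface error versus the number of training identities.

    For each identity count a predictor is trained on seeded renders of that
    many synthetic identities and evaluated on renders of held-out identities:
    landmark RMSE in normalized image units (coordinates scaled by half the
    image size) and, optionally, mean surface error after flip-flop fitting
    of the predictions. Runs at a configurable toy scale.
    """
    from .landmark_predictor import PredictorConfig, train
    from .model_fitting import fit_flip_flop
    from .shape_model import align_to_model, project_to_model, reconstruct
    from .synthetic_data import canonical_pose, random_pose, render, synthetic_family

    identity_counts = sorted(int(c) for c in identity_counts)
    nx, ny = grid
    cam = approximate_intrinsics(image_size, image_size)

    lm_reps: List[List[float]] = [[] for _ in identity_counts]
    surf_reps: List[List[float]] = [[] for _ in identity_counts]

    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        n_train_pool = identity_counts[-1]
        topo, meshes, _ = synthetic_family(
            n_train_pool + n_eval_identities, seed=rep_seed, nx=nx, ny=ny,
            n_landmarks=n_landmarks,
        )
        train_pool, eval_meshes = meshes[:n_train_pool], meshes[n_train_pool:]

        # a shape model over the training pool for surface evaluation
        model = build_pca(train_pool, 0.999, topology=topo) if fit_surface else None

        # fixed evaluation set: held-out identities, held-out render seeds
        eval_samples = []
        for mi, mesh in enumerate(eval_meshes):
            for ri in range(renders_per_eval):
                rng = np.random.default_rng([rep_seed, 7000 + mi, ri])
                pose = random_pose(mesh, cam, rng, rot_range_deg=15.0)
                eval_samples.append(
                    (render(mesh, pose, cam, topology=topo,
                            rng_seed=int(rng.integers(2 ** 31)), mesh_id=mi), mesh)
                )

        for si, count in enumerate(identity_counts):
            samples = []
            for mi in range(count):
                mesh = train_pool[mi]
                for ri in range(images_per_mesh):
                    rng = np.random.default_rng([rep_seed, mi, ri])
                    pose = random_pose(mesh, cam, rng, rot_range_deg=15.0)
                    samples.append(render(mesh, pose, cam, topology=topo,
                                          rng_seed=int(rng.integers(2 ** 31)), mesh_id=mi))
            cfg = PredictorConfig(
                image_size=image_size, n_landmarks=n_landmarks, epochs=epochs,
                seed=rep_seed,
            )
            predictor, _ = train(samples, cfg)

            sq, surf = [], []
            for sample, mesh in eval_samples:
                pred = predictor.predict(sample.image)
                res = (pred.points - sample.landmarks.points) / (image_size / 2.0)
                sq.append(np.mean(np.sum(res ** 2, axis=1)))
                if fit_surface:
                    try:
                        fit = fit_flip_flop(pred, model, cam)
                        rec = reconstruct(model, fit.coeffs)
                        aligned = align_to_model(model, mesh)
                        best = reconstruct(model, project_to_model(model, aligned))
                        surf.append(surface_error(rec, best).mean)
                    except Exception:
                        surf.append(np.nan)
            lm_reps[si].append(float(np.sqrt(np.mean(sq))))
            if fit_surface:
                surf_reps[si].append(float(np.nanmean(surf)))

    lm_curve = ScalingCurve(
        np.array(identity_counts),
        np.array([np.median(r) for r in lm_reps]),
        [np.array(r) for r in lm_reps],
        metric="landmark RMSE (normalized image units)",
    )
    surf_curve = None
    if fit_surface:
        surf_curve = ScalingCurve(
            np.array(identity_counts),
            np.array([np.median(r) for r in surf_reps]),
            [np.array(r) for r in surf_reps],
            metric="mean surface error (mm)",
        )
    return lm_curve, surf_curve


def fit_exponential(curve, sizes: Optional[np.ndarray] = None) -> ExponentialFit:
    """Fit y = a exp(-b n) + c (a, b > 0) by multi-start trust-region least squares.

    Accepts a :class:`ScalingCurve` or a plain array of errors with ``sizes``.
    The asymptote ``c`` is the extrapolated convergence point. A fit whose
    decay rate pins at the search bound (as happens for curves that increase
    with n) is flagged ``model_misfit``.
    """
    if isinstance(curve, ScalingCurve):
        x = np.asarray(curve.sizes, dtype=np.float64)
        y = np.asarray(curve.errors, dtype=np.float64)
    else:
        y = np.asarray(curve, dtype=np.float64)
        x = np.asarray(sizes, dtype=np.float64)
    if len(np.unique(x)) < 4:
        raise InsufficientDataError("exponential fit requires >= 4 distinct sizes")

    def resid(p):
        a, b, c = p
        return a * np.exp(-b * x) + c - y

    b_lo, b_hi = 1e-8, 1e3
    span = max(y.max() - y.min(), 1e-12)
    starts = [
        np.array([span, b0, y.min()])
        for b0 in (0.001, 0.01, 0.05, 0.2, 1.0, 5.0)
    ]
    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                resid, p0,
                bounds=([0.0, b_lo, -np.inf], [np.inf, b_hi, np.inf]),
                method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise InvalidParameterError("exponential fit failed from all starts")
    a, b, c = best.x
    misfit = bool(b <= 2 * b_lo or b >= 0.99 * b_hi)
    return ExponentialFit(float(a), float(b), float(c),
                          residual_sse=float(2 * best.cost), model_misfit=misfit)


def save_curve_csv(curve: ScalingCurve, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["size", "replicate", "error"])
        for size, reps in zip(curve.sizes, curve.replicate_errors):
            for ri, e in enumerate(reps):
                w.writerow([int(size), ri, f"{e:.8g}"])


def plot_curve(curve: ScalingCurve, fit: Optional[ExponentialFit], path) -> None:
    """Optional scaling-curve plot with the fitted exponential overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for size, reps in zip(curve.sizes, curve.replicate_errors):
        ax.plot([size] * len(reps), reps, ".", color="0.6", ms=4)
    ax.plot(curve.sizes, curve.errors, "o-", color="C0", label="median")
    if fit is not None:
        xs = np.linspace(curve.sizes[0], curve.sizes[-1] * 1.5, 200)
        ax.plot(xs, fit.predict(xs), "--", color="C3",
                label=f"a e^(-bn)+c, c={fit.c:.3g}")
        ax.axhline(fit.c, color="C3", lw=0.5)
    ax.set_xlabel("sample count n")
    ax.set_ylabel(curve.metric)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
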