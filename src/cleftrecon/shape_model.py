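"""PCA statistical shape model over template-corresponded palate meshes.

Meshes are rigidly pre-aligned with generalized Procrustes analysis (optional
scale normalization, default rigid-only), stacked as 3V-vectors, centered and
decomposed with a thin SVD. Mode variances follow the sample convention
singular_value^2 / (n - 1). The retained mode count is the smallest k whose
cumulative variance fraction reaches the requested threshold (default 99.9%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .core_geometry import TemplateTopology, TriMesh
from .exceptions import InsufficientDataError, InvalidParameterError, TopologyError

__all__ = [
    "ShapeModel",
    "ShapeCoefficients",
    "ErrorSummary",
    "generalized_procrustes",
    "build_pca",
    "align_to_model",
    "reconstruct",
    "project_to_model",
    "sample_coefficients",
    "reconstruction_error",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass
class ShapeCoefficients:
    """Weights of the retained eigenmodes."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if not np.all(np.isfinite(self.weights)):
            raise InvalidParameterError("coefficients must be finite")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ShapeModel:
    """Mean shape plus orthonormal eigenmodes of vertex-coordinate variation."""

    mean_shape: np.ndarray        # (3V,) stacked xyz, mm
    components: np.ndarray        # (k, 3V) orthonormal rows
    variances: np.ndarray         # (k,) mm^2, non-increasing
    topology: TemplateTopology
    n_training: int

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=np.float64).reshape(-1)
        self.components = np.asarray(self.components, dtype=np.float64).reshape(-1, len(self.mean_shape))
        self.variances = np.asarray(self.variances, dtype=np.float64).reshape(-1)
        if len(self.variances) != len(self.components):
            raise InvalidParameterError("variances/components length mismatch")
        if np.any(self.variances < -1e-12) or np.any(np.diff(self.variances) > 1e-9):
            raise InvalidParameterError("variances must be non-negative and non-increasing")

    @property
    def n_modes(self) -> int:
        return len(self.components)

    @property
    def n_vertices(self) -> int:
        return len(self.mean_shape) // 3

    @property
    def mean_vertices(self) -> np.ndarray:
        return self.mean_shape.reshape(-1, 3)

    def mean_mesh(self) -> TriMesh:
        return TriMesh(self.mean_vertices.copy(), self.topology.faces)


@dataclass
class ErrorSummary:
    """Per-vertex Euclidean error summary in mm."""

    mean: float
    max: float
    per_vertex: np.ndarray


def _kabsch(source: np.ndarray, target: np.ndarray, with_scaling: bool):
    """Similarity (or rigid) alignment of source onto target, both V x 3."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    s0, t0 = source - sc, target - tc
    h = s0.T @ t0
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    if with_scaling:
        scale = (sv * np.diag(diag)).sum() / (s0 ** 2).sum()
    else:
        scale = 1.0
    trans = tc - scale * rot @ sc
    return rot, scale, trans


def generalized_procrustes(
    vertex_sets: Sequence[np.ndarray],
    with_scaling: bool = False,
    max_iter: int = 10,
    tol: float = 1e-10,
) -> List[np.ndarray]:
    """Iteratively align all vertex sets to their evolving mean shape."""
    aligned = [np.asarray(v, dtype=np.float64).copy() for v in vertex_sets]
    ref = aligned[0] - aligned[0].mean(axis=0)
    prev = np.inf
    for _ in range(max_iter):
        for i, v in enumerate(aligned):
            rot, s, t = _kabsch(v, ref, with_scaling)
            aligned[i] = s * v @ rot.T + t
        mean = np.mean(aligned, axis=0)
        mean -= mean.mean(axis=0)
        change = float(np.linalg.norm(mean - ref) / max(np.linalg.norm(ref), 1e-12))
        ref = mean
        if abs(prev - change) < tol or change < tol:
            break
        prev = change
    return aligned


def build_pca(
    meshes: Sequence[TriMesh],
    variance_threshold: float = 0.999,
    topology: Optional[TemplateTopology] = None,
    align: bool = True,
    procrustes_scaling: bool = False,
) -> ShapeModel:
    """Build the PCA shape model from template-corresponded meshes.

    Retains the smallest number of eigenmodes whose cumulative variance
    fraction is at least ``variance_threshold``.
    """
    if len(meshes) < 2:
        raise InsufficientDataError("PCA model requires at least 2 meshes")
    if not (0 < variance_threshold <= 1.0):
        raise InvalidParameterError("variance_threshold must be in (0, 1]")
    v0 = meshes[0].n_vertices
    for m in meshes:
        if m.n_vertices != v0:
            raise TopologyError("all meshes must share the template vertex count")
    if topology is None:
        topology = TemplateTopology(faces=meshes[0].faces, n_vertices=v0)

    verts = [m.vertices for m in meshes]
    if align:
        verts = generalized_procrustes(verts, with_scaling=procrustes_scaling)
    x = np.stack([v.reshape(-1) for v in verts])  # (n, 3V)
    n = len(x)
    mean = x.mean(axis=0)
    xc = x - mean
    # thin SVD; rank of centered data is at most n - 1
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    r = min(n - 1, xc.shape[1])
    s, vt = s[:r], vt[:r]
    variances = s ** 2 / (n - 1)
    total = variances.sum()
    if total <= 0:
        k = 1
    else:
        frac = np.cumsum(variances) / total
        k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
        k = min(k, r)
    return ShapeModel(mean, vt[:k], variances[:k], topology, n_training=n)


def reconstruct(model: ShapeModel, coeffs) -> TriMesh:
    """Mean shape plus the weighted eigenmodes, as a template-topology mesh."""
    w = coeffs.weights if isinstance(coeffs, ShapeCoefficients) else np.asarray(coeffs, dtype=np.float64)
    if len(w) != model.n_modes:
        raise InvalidParameterError(
            f"expected {model.n_modes} coefficients, got {len(w)}"
        )
    flat = model.mean_shape + model.components.T @ w
    return TriMesh(flat.reshape(-1, 3), model.topology.faces)


def align_to_model(model: ShapeModel, mesh: TriMesh, with_scaling: bool = False) -> TriMesh:
    """Rigidly align a corresponded mesh to the model's mean-shape frame.

    Training meshes are Procrustes-aligned internally by :func:`build_pca`,
    so a raw mesh must be brought into the same frame before encoding or
    error evaluation against the model.
    """
    if mesh.n_vertices != model.n_vertices:
        raise TopologyError("mesh does not match the model template")
    rot, s, t = _kabsch(mesh.vertices, model.mean_vertices, with_scaling)
    return TriMesh(s * mesh.vertices @ rot.T + t, mesh.faces, mesh.vertex_colors)


def project_to_model(model: ShapeModel, mesh: TriMesh) -> ShapeCoefficients:
    """Orthogonal projection of a corresponded mesh onto the model subspace."""
    if mesh.n_vertices != model.n_vertices:
        raise TopologyError("mesh does not match the model template")
    return ShapeCoefficients(model.components @ (mesh.vertices.reshape(-1) - model.mean_shape))


def sample_coefficients(model: ShapeModel, rng) -> ShapeCoefficients:
    """Draw in-distribution coefficients, independent zero-mean Gaussians per mode."""
    if model.n_modes < 1:
        raise InvalidParameterError("model has no modes to sample")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return ShapeCoefficients(rng.normal(0.0, 1.0, model.n_modes) * np.sqrt(model.variances))


def reconstruction_error(
    model: ShapeModel, mesh: TriMesh, region: Optional[np.ndarray] = None,
    align: bool = True,
) -> ErrorSummary:
    """Project-and-reconstruct error of a mesh under the (truncated) model.

    By default the mesh is rigidly aligned to the model frame first, matching
    the Procrustes pre-alignment applied to the training meshes.
    """
    if align:
        mesh = align_to_model(model, mesh)
    coeffs = project_to_model(model, mesh)
    rec = reconstruct(model, coeffs)
    d = np.linalg.norm(rec.vertices - mesh.vertices, axis=1)
    if region is not None:
        region = np.asarray(region, dtype=np.int64)
        if region.size == 0:
            raise InvalidParameterError("region must be non-empty")
        d = d[region]
    return ErrorSummary(float(d.mean()), float(d.max()), d)


def save_model(model: ShapeModel, path) -> None:
    """Serialize to an npz container with a versioned JSON header."""
    header = {
        "format": "cleftrecon-shape-model",
        "version": _FORMAT_VERSION,
        "n_training": model.n_training,
        "n_vertices": model.n_vertices,
        "n_modes": model.n_modes,
    }
    np.savez_compressed(
        str(path),
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        mean_shape=model.mean_shape,
        components=model.components,
        variances=model.variances,
        faces=model.topology.faces,
        contact_region=model.topology.contact_region,
        landmark_subset=model.topology.landmark_subset,
        n_vertices=np.array([model.topology.n_vertices]),
    )


def load_model(path) -> ShapeModel:
    path = str(path)
    if not path.endswith(".npz"):
        path_obj = Path(path)
        if not path_obj.exists() and Path(path + ".npz").exists():
            path = path + ".npz"
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header.get("format") != "cleftrecon-shape-model":
            raise InvalidParameterError("not a cleftrecon shape model archive")
        topo = TemplateTopology(
            faces=z["faces"],
            n_vertices=int(z["n_vertices"][0]),
            contact_region=z["contact_region"],
            landmark_subset=z["landmark_subset"],
        )
        return ShapeModel(
            z["mean_shape"], z["components"], z["variances"], topo,
            n_training=int(header["n_training"]),
        )
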