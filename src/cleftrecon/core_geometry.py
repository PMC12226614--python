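"""Mesh/image data model, pinhole projection and similarity-pose estimation.

The camera model is the classical pinhole projection

    z_c * [u, v, 1]^T = K [R | T] (s * X_w, 1)^T

with intrinsics ``K = [[fx, 0, cx], [0, fy, cy], [0, 0, 1]]``, a similarity
pose consisting of a rotation ``R``, translation ``T`` (mm) and a single
global scale ``s`` applied to world points before the rigid transform, and
per-point homogeneous normalization by the camera-frame depth ``z_c``.

Image coordinates are (u, v) with origin at the top-left, u rightward,
v downward, 0-based, and pixel centers at integer coordinates.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh as _trimesh
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .exceptions import (
    BehindCameraError,
    ConvergenceError,
    InsufficientCorrespondencesError,
    InvalidParameterError,
    TopologyError,
)

__all__ = [
    "TriMesh",
    "TemplateTopology",
    "CameraIntrinsics",
    "SimilarityPose",
    "Landmarks2D",
    "CorrespondenceSet",
    "PoseEstimateInfo",
    "project",
    "approximate_intrinsics",
    "estimate_pose",
    "load_mesh",
    "save_mesh",
    "load_landmarks",
    "save_landmarks",
    "load_correspondences",
    "save_correspondences",
]

_MIN_CORRESPONDENCES = 4
_ORTHO_TOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Triangle mesh in template correspondence; coordinates in mm."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidParameterError("vertices must be V x 3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidParameterError("faces must be F x 3")
        if len(self.vertices) < 3 or len(self.faces) < 1:
            raise InvalidParameterError("need V >= 3 and F >= 1")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidParameterError("vertex coordinates must be finite")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise TopologyError("face indices out of range")
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.float64)
            if self.vertex_colors.shape != (len(self.vertices), 3):
                raise InvalidParameterError("vertex_colors must be V x 3")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.vertices - self.centroid, axis=1).max())

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_colors is None else self.vertex_colors.copy(),
        )


@dataclass
class TemplateTopology:
    """Fixed template connectivity plus the clinically relevant vertex subsets.

    ``contact_region`` marks the alveolar-ridge area that touches the
    orthodontic plate; ``landmark_subset`` is the sub-sampled vertex set used
    as dense 2D landmarks (default size 1000 out of 10000 template vertices).
    """

    faces: np.ndarray
    n_vertices: int = 10000
    contact_region: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    landmark_subset: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.contact_region = np.asarray(self.contact_region, dtype=np.int64)
        self.landmark_subset = np.asarray(self.landmark_subset, dtype=np.int64)
        for name, idx in (("contact_region", self.contact_region), ("landmark_subset", self.landmark_subset)):
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_vertices):
                raise TopologyError(f"{name} indices out of [0, {self.n_vertices})")


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidParameterError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise InvalidParameterError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def scaled(self, k: float) -> "CameraIntrinsics":
        """Intrinsics for an image resized by factor ``k``."""
        return CameraIntrinsics(
            self.fx * k, self.fy * k, self.cx * k, self.cy * k,
            int(round(self.width * k)), int(round(self.height * k)),
        )


@dataclass
class SimilarityPose:
    """Similarity transform: X_cam = scale * R @ X_world + T."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.rotation.shape == (3,):
            self.rotation = Rotation.from_rotvec(self.rotation).as_matrix()
        if self.rotation.shape != (3, 3):
            raise InvalidParameterError("rotation must be 3x3 or an axis-angle triple")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise InvalidParameterError(f"rotation not orthonormal (|R^T R - I| = {err:g})")
        if err > _ORTHO_TOL:
            # re-orthonormalize tiny drift
            u, _, vt = np.linalg.svd(self.rotation)
            self.rotation = u @ vt
        if np.linalg.det(self.rotation) < 0:
            raise InvalidParameterError("rotation must be proper (det = +1)")
        if not self.scale > 0:
            raise InvalidParameterError("scale must be positive")

    def as_params(self) -> np.ndarray:
        """Minimal 7-parameter encoding [rotvec, translation, log scale]."""
        return np.concatenate(
            [Rotation.from_matrix(self.rotation).as_rotvec(), self.translation, [math.log(self.scale)]]
        )

    @classmethod
    def from_params(cls, p: np.ndarray) -> "SimilarityPose":
        p = np.asarray(p, dtype=np.float64)
        return cls(Rotation.from_rotvec(p[:3]).as_matrix(), p[3:6], math.exp(p[6]))

    @classmethod
    def identity(cls) -> "SimilarityPose":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points into the camera frame."""
        return (self.scale * np.asarray(points)) @ self.rotation.T + self.translation

    def projection_matrix(self, cam: CameraIntrinsics) -> np.ndarray:
        """The 3x4 matrix K [sR | T]."""
        rt = np.hstack([self.scale * self.rotation, self.translation[:, None]])
        return cam.matrix @ rt


@dataclass
class Landmarks2D:
    """Per-vertex image-space annotations with optional predicted variance (px^2)."""

    points: np.ndarray
    sigma2: Optional[np.ndarray] = None
    in_bounds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidParameterError("points must be L x 2")
        if not np.all(np.isfinite(self.points)):
            raise InvalidParameterError("landmark coordinates must be finite")
        if self.sigma2 is not None:
            self.sigma2 = np.asarray(self.sigma2, dtype=np.float64).reshape(-1)
            if len(self.sigma2) != len(self.points):
                raise InvalidParameterError("sigma2 length mismatch")
            if np.any(self.sigma2 <= 0):
                raise InvalidParameterError("sigma2 must be strictly positive")
        if self.in_bounds is not None:
            self.in_bounds = np.asarray(self.in_bounds, dtype=bool).reshape(-1)
            if len(self.in_bounds) != len(self.points):
                raise InvalidParameterError("in_bounds length mismatch")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CorrespondenceSet:
    """Sparse links between template vertex ids and image locations."""

    vertex_ids: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64).reshape(-1)
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.vertex_ids) != len(self.points):
            raise InvalidParameterError("vertex_ids and points length mismatch")
        if len(self.vertex_ids) < 1:
            raise InvalidParameterError("need at least one correspondence")
        if len(np.unique(self.vertex_ids)) != len(self.vertex_ids):
            raise InvalidParameterError("vertex_ids must be unique")

    def __len__(self) -> int:
        return len(self.vertex_ids)

    @classmethod
    def from_pairs(cls, pairs: Sequence) -> "CorrespondenceSet":
        ids = [p[0] for p in pairs]
        pts = [p[1] for p in pairs]
        return cls(np.array(ids), np.array(pts))


@dataclass
class PoseEstimateInfo:
    """Diagnostics from :func:`estimate_pose`."""

    rms_px: float
    initial_rms_px: float
    n_evaluations: int
    n_starts: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def project(points3d: np.ndarray, pose: SimilarityPose, cam: CameraIntrinsics) -> Landmarks2D:
    """Project 3D world points (mm) to image coordinates.

    Raises :class:`BehindCameraError` if any point has camera-frame depth <= 0.
    """
    pts = np.asarray(points3d, dtype=np.float64).reshape(-1, 3)
    xc = pose.apply(pts)
    z = xc[:, 2]
    bad = np.nonzero(z <= 0)[0]
    if bad.size:
        raise BehindCameraError(bad)
    u = cam.fx * xc[:, 0] / z + cam.cx
    v = cam.fy * xc[:, 1] / z + cam.cy
    in_bounds = (
        (u >= -0.5) & (u <= cam.width - 0.5) & (v >= -0.5) & (v <= cam.height - 0.5)
    )
    return Landmarks2D(np.column_stack([u, v]), in_bounds=in_bounds)


def project_depths(points3d: np.ndarray, pose: SimilarityPose) -> np.ndarray:
    """Camera-frame depths of world points (helper for rendering/fitting)."""
    return pose.apply(np.asarray(points3d).reshape(-1, 3))[:, 2]


def approximate_intrinsics(
    width: int, height: int, fov_deg: float = 53.0
) -> CameraIntrinsics:
    """Approximate intrinsics from image size and a horizontal field of view.

    Default 53 degrees, a typical smartphone main camera. The principal point
    is placed at the image center and fx = fy = (width/2) / tan(fov/2).
    """
    if width < 1 or height < 1:
        raise InvalidParameterError("image size must be at least 1 x 1")
    if not (1.0 < fov_deg < 179.0):
        raise InvalidParameterError("fov must be in (1, 179) degrees")
    f = (width / 2.0) / math.tan(math.radians(fov_deg) / 2.0)
    return CameraIntrinsics(f, f, width / 2.0, height / 2.0, width, height)


def default_initial_pose(points3d: np.ndarray) -> SimilarityPose:
    """Identity rotation, unit scale, centroid placed at depth 4x bounding radius.

    Guarantees positive depth at the first objective evaluation.
    """
    pts = np.asarray(points3d).reshape(-1, 3)
    c = pts.mean(axis=0)
    r = float(np.linalg.norm(pts - c, axis=1).max())
    r = max(r, 1e-6)
    t = np.array([0.0, 0.0, 4.0 * r]) - c
    return SimilarityPose(np.eye(3), t, 1.0)


def _pose_residuals(
    p: np.ndarray, pts3d: np.ndarray, target: np.ndarray, cam: CameraIntrinsics,
    sqrt_w: np.ndarray,
) -> np.ndarray:
    rot = Rotation.from_rotvec(p[:3]).as_matrix()
    s = math.exp(min(p[6], 50.0))
    xc = (s * pts3d) @ rot.T + p[3:6]
    z = xc[:, 2]
    zc = np.maximum(z, 1e-9)
    u = cam.fx * xc[:, 0] / zc + cam.cx
    v = cam.fy * xc[:, 1] / zc + cam.cy
    res = np.column_stack([u, v]) - target
    res *= sqrt_w[:, None]
    # soft barrier keeping points in front of the camera
    barrier = 1e4 * np.maximum(0.0, 1e-3 - z)
    return np.concatenate([res.ravel(), barrier])


_CANONICAL_ROTVECS = [
    np.zeros(3),
    np.array([math.pi, 0, 0]),
    np.array([0, math.pi, 0]),
    np.array([0, 0, math.pi]),
    np.array([math.pi / 2, 0, 0]),
    np.array([-math.pi / 2, 0, 0]),
    np.array([0, math.pi / 2, 0]),
    np.array([0, -math.pi / 2, 0]),
]


def estimate_pose(
    corr: CorrespondenceSet,
    template_points: np.ndarray,
    cam: CameraIntrinsics,
    init: Optional[SimilarityPose] = None,
    weights: Optional[np.ndarray] = None,
    multistart: bool = True,
    good_rms_px: float = 1.0,
    return_info: bool = False,
):
    """Estimate the similarity pose from sparse 2D-3D correspondences.

    Iterative damped nonlinear least squares over rotation (axis-angle),
    translation and log-scale, minimizing the (optionally weighted) sum of
    squared reprojection residuals in pixels. Requires at least 4
    correspondences. When the fit from the provided (or default)
    initialization remains above ``good_rms_px``, additional starts from
    canonical rotations are tried and the best kept.
    """
    if len(corr) < _MIN_CORRESPONDENCES:
        raise InsufficientCorrespondencesError(
            f"pose estimation requires >= {_MIN_CORRESPONDENCES} correspondences, got {len(corr)}"
        )
    template_points = np.asarray(template_points, dtype=np.float64).reshape(-1, 3)
    if corr.vertex_ids.max() >= len(template_points):
        raise TopologyError("correspondence vertex id out of range")
    pts3d = template_points[corr.vertex_ids]
    target = corr.points
    if weights is None:
        sqrt_w = np.ones(len(corr))
    else:
        weights = np.asarray(weights, dtype=np.float64).reshape(-1)
        if np.any(weights < 0):
            raise InvalidParameterError("weights must be non-negative")
        sqrt_w = np.sqrt(weights)

    def solve_from(p0: np.ndarray):
        return least_squares(
            _pose_residuals,
            p0,
            args=(pts3d, target, cam, sqrt_w),
            method="lm" if 2 * len(corr) + len(corr) >= 7 else "trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )

    def rms_of(res_vec: np.ndarray) -> float:
        uv = res_vec[: 2 * len(corr)]
        return float(np.sqrt(np.mean(uv.reshape(-1, 2) ** 2).sum()))

    base_init = init if init is not None else default_initial_pose(pts3d)
    p0 = base_init.as_params()
    initial_rms = rms_of(_pose_residuals(p0, pts3d, target, cam, sqrt_w))

    best = solve_from(p0)
    n_starts = 1
    if multistart and rms_of(best.fun) > good_rms_px:
        centroid = pts3d.mean(axis=0)
        r = max(float(np.linalg.norm(pts3d - centroid, axis=1).max()), 1e-6)
        for rv in _CANONICAL_ROTVECS[1:]:
            rot = Rotation.from_rotvec(rv).as_matrix()
            t = np.array([0.0, 0.0, 4.0 * r]) - rot @ centroid
            p_try = np.concatenate([rv, t, [0.0]])
            sol = solve_from(p_try)
            n_starts += 1
            if sol.cost < best.cost:
                best = sol
            if rms_of(best.fun) <= good_rms_px:
                break
    if not np.isfinite(best.cost):
        raise ConvergenceError("pose optimization produced a non-finite cost")
    pose = SimilarityPose.from_params(best.x)
    if return_info:
        info = PoseEstimateInfo(
            rms_px=rms_of(best.fun),
            initial_rms_px=initial_rms,
            n_evaluations=int(best.nfev),
            n_starts=n_starts,
        )
        return pose, info
    return pose


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_mesh(path) -> TriMesh:
    """Load an OBJ/PLY mesh preserving vertex order (template correspondence)."""
    tm = _trimesh.load(str(path), process=False, maintain_order=True, force="mesh")
    colors = None
    visual = getattr(tm, "visual", None)
    if visual is not None and getattr(visual, "kind", None) == "vertex":
        vc = np.asarray(visual.vertex_colors, dtype=np.float64)
        if vc.shape[0] == len(tm.vertices):
            colors = vc[:, :3] / 255.0
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), colors)


def save_mesh(mesh: TriMesh, path) -> None:
    kw = {}
    if mesh.vertex_colors is not None:
        kw["vertex_colors"] = (np.clip(mesh.vertex_colors, 0, 1) * 255).astype(np.uint8)
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False, **kw)
    tm.export(str(path))


def save_landmarks(lm: Landmarks2D, path, image: Optional[str] = None,
                   width: Optional[int] = None, height: Optional[int] = None) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["id", "u", "v"] + (["sigma2"] if lm.sigma2 is not None else [])
            w.writerow(header)
            for i, (u, v) in enumerate(lm.points):
                row = [i, repr(float(u)), repr(float(v))]
                if lm.sigma2 is not None:
                    row.append(repr(float(lm.sigma2[i])))
                w.writerow(row)
        return
    obj = {"points": lm.points.tolist()}
    if lm.sigma2 is not None:
        obj["sigma2"] = lm.sigma2.tolist()
    if image is not None:
        obj["image"] = image
    if width is not None:
        obj["width"] = width
    if height is not None:
        obj["height"] = height
    path.write_text(json.dumps(obj))


def load_landmarks(path) -> Landmarks2D:
    path = Path(path)
    if path.suffix == ".csv":
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        pts = np.array([[float(r["u"]), float(r["v"])] for r in rows])
        sigma2 = None
        if rows and "sigma2" in rows[0] and rows[0]["sigma2"] not in (None, ""):
            sigma2 = np.array([float(r["sigma2"]) for r in rows])
        return Landmarks2D(pts, sigma2=sigma2)
    obj = json.loads(path.read_text())
    return Landmarks2D(
        np.asarray(obj["points"], dtype=np.float64),
        sigma2=np.asarray(obj["sigma2"], dtype=np.float64) if "sigma2" in obj else None,
    )


def save_correspondences(corr: CorrespondenceSet, path) -> None:
    rows = [
        {"vertex_id": int(i), "u": float(u), "v": float(v)}
        for i, (u, v) in zip(corr.vertex_ids, corr.points)
    ]
    Path(path).write_text(json.dumps(rows))


def load_correspondences(path) -> CorrespondenceSet:
    rows = json.loads(Path(path).read_text())
    return CorrespondenceSet(
        np.array([r["vertex_id"] for r in rows]),
        np.array([[r["u"], r["v"]] for r in rows]),
    )
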