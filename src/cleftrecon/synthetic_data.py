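"""Synthetic palate meshes and rendered training data.

Stands in for clinical intraoral scans and artist-tuned renders: a parametric
dome surface on a fixed rectangular grid (so every generated mesh is in
template correspondence by construction) with two alveolar-ridge bulges
merging into an anterior ridge arc, a variable cleft gap of controllable
width and laterality, and seeded smooth random displacement. Images come
from a deterministic z-buffered software rasterizer with flat Lambertian
shading, a noise background and optional linear motion blur; landmark
annotations are exact projections of the template's landmark subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import convolve
from scipy.spatial.transform import Rotation

from .core_geometry import (
    CameraIntrinsics,
    Landmarks2D,
    SimilarityPose,
    TemplateTopology,
    TriMesh,
    approximate_intrinsics,
    project,
)
from .exceptions import BehindCameraError, InvalidParameterError

__all__ = [
    "PalateParams",
    "SyntheticSample",
    "make_grid_topology",
    "default_template",
    "generate_palate",
    "sample_params",
    "synthetic_family",
    "canonical_pose",
    "random_pose",
    "render",
    "make_dataset",
]


@dataclass
class PalateParams:
    """Generative parameters of one synthetic palate (all lengths in mm).

    ``cleft_laterality`` is a signed lateral offset of the cleft gap; its sign
    encodes the side. ``noise_amplitude`` controls smooth per-identity shape
    variation.
    """

    dome_width: float = 34.0
    dome_length: float = 38.0
    dome_height: float = 10.0
    ridge_height: float = 4.0
    ridge_width: float = 4.0
    cleft_width: float = 8.0
    cleft_laterality: float = 3.0
    noise_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dome_width", "dome_length", "dome_height", "ridge_height", "ridge_width"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.cleft_width < 0:
            raise InvalidParameterError("cleft_width must be >= 0")
        if self.noise_amplitude < 0:
            raise InvalidParameterError("noise_amplitude must be >= 0")


@dataclass
class SyntheticSample:
    """One rendered image with exact landmark annotations."""

    image: np.ndarray              # (H, W, 3) in [0, 1]
    landmarks: Landmarks2D         # over the template landmark_subset
    visible: np.ndarray            # per-landmark z-buffer visibility bit
    pose: SimilarityPose
    cam: CameraIntrinsics
    mesh_id: int
    seed: int


# ---------------------------------------------------------------------------
# parametric surface
# ---------------------------------------------------------------------------

_RIDGE_POS = 0.68      # lateral ridge crest position, fraction of half-width
_ANTERIOR_POS = 0.62   # anterior ridge arc position, fraction of half-length


def _grid_coords(nx: int, ny: int, width: float, length: float):
    xi = np.linspace(-1.0, 1.0, nx)
    eta = np.linspace(-1.0, 1.0, ny)
    x = xi[None, :] * width / 2.0          # (ny, nx) lateral
    y = eta[:, None] * length / 2.0        # anterior toward +y
    return np.broadcast_to(x, (ny, nx)).copy(), np.broadcast_to(y, (ny, nx)).copy()


def _ridge_field(x: np.ndarray, y: np.ndarray, p: PalateParams) -> np.ndarray:
    """Horseshoe-shaped ridge activation in [0, 1]."""
    xr = _RIDGE_POS * p.dome_width / 2.0
    yf = _ANTERIOR_POS * p.dome_length / 2.0
    # ridge_width is the full width of the ridge band (sigma = width / 2)
    s2 = p.ridge_width ** 2 / 2.0
    lateral = np.exp(-((np.abs(x) - xr) ** 2) / s2)
    lateral *= 1.0 / (1.0 + np.exp(-(y + 0.6 * p.dome_length / 2.0) / 2.0))
    anterior = np.exp(-((y - yf) ** 2) / s2) * np.exp(-(x ** 2) / (2.0 * xr ** 2) * 0.5)
    return 1.0 - (1.0 - lateral) * (1.0 - anterior)


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v00 = (iy * nx + ix).ravel()
    v10 = v00 + 1
    v01 = v00 + nx
    v11 = v01 + 1
    return np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )


def make_grid_topology(
    nx: int = 100,
    ny: int = 100,
    n_landmarks: Optional[int] = None,
    ridge_weight: float = 4.0,
    seed: int = 0,
) -> TemplateTopology:
    """Template topology for the nx x ny palate grid.

    The contact region is derived from the canonical (cleft-free) ridge field;
    the landmark subset, when requested, comes from weighted farthest-point
    sub-sampling with the given ridge emphasis.
    """
    canonical = replace(PalateParams(), cleft_width=0.0, noise_amplitude=0.0)
    x, y = _grid_coords(nx, ny, canonical.dome_width, canonical.dome_length)
    field = _ridge_field(x, y, canonical)
    contact = np.nonzero(field.ravel() > 0.5)[0]
    topo = TemplateTopology(
        faces=_grid_faces(nx, ny),
        n_vertices=nx * ny,
        contact_region=contact,
    )
    if n_landmarks is not None:
        from .landmark_predictor import subsample_landmarks

        topo.landmark_subset = subsample_landmarks(
            topo, n_landmarks, ridge_weight=ridge_weight, seed=seed
        )
    return topo


@lru_cache(maxsize=4)
def default_template(n_landmarks: int = 1000) -> TemplateTopology:
    """The default 10000-vertex template with a 1000-point landmark subset."""
    return make_grid_topology(100, 100, n_landmarks=n_landmarks)


def _smooth_noise(rng: np.random.Generator, ny: int, nx: int, amplitude: float,
                  coarse: int = 6) -> np.ndarray:
    coarse_grid = rng.normal(0.0, amplitude, size=(coarse, coarse))
    sp = RectBivariateSpline(
        np.linspace(0, 1, coarse), np.linspace(0, 1, coarse), coarse_grid, kx=3, ky=3
    )
    return sp(np.linspace(0, 1, ny), np.linspace(0, 1, nx))


def generate_palate(params: PalateParams, nx: int = 100, ny: int = 100) -> TriMesh:
    """Generate a palate-like dome mesh with ridges and a cleft gap.

    The topology is fixed for given grid dimensions, so meshes generated with
    different parameters are in template correspondence by construction.
    """
    p = params
    x, y = _grid_coords(nx, ny, p.dome_width, p.dome_length)
    xi = 2.0 * x / p.dome_width
    eta = 2.0 * y / p.dome_length

    z = p.dome_height * (1.0 - xi ** 2) * (1.0 - eta ** 2)
    field = _ridge_field(x, y, p)
    z = z + p.ridge_height * field

    # cleft: smooth gap of the requested width at the stated laterality,
    # cutting through the anterior half; depth and lateral push both scale
    # with cleft_width so a zero-width cleft leaves the surface untouched.
    if p.cleft_width > 0:
        half = p.cleft_width / 2.0
        g = np.exp(-((x - p.cleft_laterality) ** 2) / (2.0 * half ** 2))
        s = 1.0 / (1.0 + np.exp(-(y - 0.1 * p.dome_length / 2.0) / 3.0))
        amp = p.cleft_width / (p.cleft_width + 2.0)
        z = z - (0.5 * p.dome_height + p.ridge_height) * amp * g * s
        push = 0.5 * p.cleft_width * g * s * np.tanh((x - p.cleft_laterality) / (half + 1.0))
        x = x + push

    if p.noise_amplitude > 0:
        rng = np.random.default_rng(p.seed)
        z = z + _smooth_noise(rng, ny, nx, p.noise_amplitude)

    vertices = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    # mucosa-like coloring: pink base, lighter ridges, mild seeded mottling
    base = np.array([0.78, 0.45, 0.45])
    colors = np.tile(base, (nx * ny, 1)) + 0.12 * field.ravel()[:, None]
    rng_c = np.random.default_rng(p.seed + 1)
    colors += 0.05 * _smooth_noise(rng_c, ny, nx, 1.0).ravel()[:, None]
    colors = np.clip(colors, 0.0, 1.0)

    return TriMesh(vertices, _grid_faces(nx, ny), vertex_colors=colors)


def sample_params(rng: np.random.Generator, base: Optional[PalateParams] = None) -> PalateParams:
    """Draw identity-level generative parameters for a synthetic family."""
    b = base or PalateParams()
    return PalateParams(
        dome_width=float(b.dome_width + rng.normal(0, 2.0)),
        dome_length=float(b.dome_length + rng.normal(0, 2.5)),
        dome_height=float(b.dome_height + rng.normal(0, 1.0)),
        ridge_height=float(max(1.0, b.ridge_height + rng.normal(0, 0.5))),
        ridge_width=float(max(2.0, b.ridge_width + rng.normal(0, 0.3))),
        cleft_width=float(rng.uniform(2.0, 12.0)),
        cleft_laterality=float(rng.uniform(-6.0, 6.0)),
        noise_amplitude=b.noise_amplitude,
        seed=int(rng.integers(2 ** 31)),
    )


def synthetic_family(
    n_identities: int,
    seed: int = 0,
    nx: int = 100,
    ny: int = 100,
    n_landmarks: Optional[int] = None,
    ridge_weight: float = 4.0,
) -> Tuple[TemplateTopology, List[TriMesh], List[PalateParams]]:
    """A seeded family of corresponded palate meshes plus their topology."""
    rng = np.random.default_rng(seed)
    topo = make_grid_topology(nx, ny, n_landmarks=n_landmarks, ridge_weight=ridge_weight)
    params = [sample_params(rng) for _ in range(n_identities)]
    meshes = [generate_palate(p, nx, ny) for p in params]
    return topo, meshes, params


# ---------------------------------------------------------------------------
# camera placement
# ---------------------------------------------------------------------------


def canonical_pose(mesh: TriMesh, cam: CameraIntrinsics, margin: float = 0.38) -> SimilarityPose:
    """Mirror-view pose: palate facing the camera, centered, filling ~2*margin
    of the smaller image dimension."""
    r0 = Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    r = mesh.bounding_radius
    d = cam.fx * r / (margin * min(cam.width, cam.height))
    t = np.array([0.0, 0.0, d]) - r0 @ mesh.centroid
    return SimilarityPose(r0, t, 1.0)


def random_pose(
    mesh: TriMesh,
    cam: CameraIntrinsics,
    rng: np.random.Generator,
    rot_range_deg: float = 20.0,
    dist_jitter: float = 0.15,
) -> SimilarityPose:
    """Randomized camera pose around the canonical mirror view."""
    base = canonical_pose(mesh, cam)
    angles = rng.uniform(-rot_range_deg, rot_range_deg, 3)
    dr = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    rot = dr @ base.rotation
    d0 = (base.rotation @ mesh.centroid + base.translation)[2]
    d = d0 * (1.0 + rng.uniform(-dist_jitter, dist_jitter))
    t = np.array([0.0, 0.0, d]) - rot @ mesh.centroid
    return SimilarityPose(rot, t, 1.0)


# ---------------------------------------------------------------------------
# rasterizer
# ---------------------------------------------------------------------------


def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    coarse = rng.uniform(0.1, 0.45, size=(max(2, h // 16), max(2, w // 16), 3))
    sp_axes = (np.linspace(0, 1, coarse.shape[0]), np.linspace(0, 1, coarse.shape[1]))
    out = np.empty((h, w, 3))
    for c in range(3):
        sp = RectBivariateSpline(sp_axes[0], sp_axes[1], coarse[:, :, c], kx=1, ky=1)
        out[:, :, c] = sp(np.linspace(0, 1, h), np.linspace(0, 1, w))
    return np.clip(out, 0.0, 1.0)


def _motion_blur(image: np.ndarray, blur_px: float, angle: float) -> np.ndarray:
    n = int(np.ceil(blur_px))
    if n < 1:
        return image
    size = 2 * n + 1
    kernel = np.zeros((size, size))
    ts = np.linspace(-blur_px / 2.0, blur_px / 2.0, 4 * size)
    for t in ts:
        i = int(round(n + t * np.sin(angle)))
        j = int(round(n + t * np.cos(angle)))
        kernel[i, j] += 1.0
    kernel /= kernel.sum()
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[:, :, c] = convolve(image[:, :, c], kernel, mode="nearest")
    return out


def render(
    mesh: TriMesh,
    pose: SimilarityPose,
    cam: CameraIntrinsics,
    topology: Optional[TemplateTopology] = None,
    light_dir: Optional[Sequence[float]] = None,
    blur_px: float = 0.0,
    rng_seed: int = 0,
    ambient: float = 0.15,
    mesh_id: int = 0,
) -> SyntheticSample:
    """Rasterize the mesh and return the image with exact landmark annotations.

    Flat Lambertian shading with per-face albedo from vertex colors (white if
    absent), z-buffered, over a seeded noise background. Landmarks are the
    exact projections of the landmark-subset vertices; occluded landmarks keep
    their projected coordinates and are flagged by the z-buffer visibility bit.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = cam.height, cam.width
    subset = (
        topology.landmark_subset
        if topology is not None and topology.landmark_subset.size
        else np.arange(mesh.n_vertices)
    )

    xc = pose.apply(mesh.vertices)
    z = xc[:, 2]
    bad = np.nonzero(z[subset] <= 0)[0]
    if bad.size:
        raise BehindCameraError(subset[bad])

    zsafe = np.maximum(z, 1e-9)
    u = cam.fx * xc[:, 0] / zsafe + cam.cx
    v = cam.fy * xc[:, 1] / zsafe + cam.cy

    light = np.array([0.0, 0.0, 1.0]) if light_dir is None else np.asarray(light_dir, float)
    light = light / np.linalg.norm(light)

    image = _background(rng, h, w)
    zbuf = np.full((h, w), np.inf)

    faces = mesh.faces
    tri_u, tri_v = u[faces], v[faces]
    tri_z = z[faces]
    if mesh.vertex_colors is not None:
        face_albedo = mesh.vertex_colors[faces].mean(axis=1)
    else:
        face_albedo = np.ones((len(faces), 3))

    # per-face camera-space normals, oriented toward the camera
    p0, p1, p2 = xc[faces[:, 0]], xc[faces[:, 1]], xc[faces[:, 2]]
    normals = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(normals, axis=1)
    ok_n = norms > 1e-12
    normals[ok_n] /= norms[ok_n][:, None]
    flip = normals[:, 2] > 0
    normals[flip] *= -1.0
    intensity = ambient + (1.0 - ambient) * np.maximum(0.0, -(normals @ light))

    front = np.all(tri_z > 1e-6, axis=1) & ok_n
    for f in np.nonzero(front)[0]:
        ub, vb = tri_u[f], tri_v[f]
        x0 = max(int(np.floor(ub.min())), 0)
        x1 = min(int(np.ceil(ub.max())), w - 1)
        y0 = max(int(np.floor(vb.min())), 0)
        y1 = min(int(np.ceil(vb.max())), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        d = (ub[1] - ub[0]) * (vb[2] - vb[0]) - (vb[1] - vb[0]) * (ub[2] - ub[0])
        if abs(d) < 1e-12:
            continue
        w1 = ((gx - ub[0]) * (vb[2] - vb[0]) - (gy - vb[0]) * (ub[2] - ub[0])) / d
        w2 = ((gy - vb[0]) * (ub[1] - ub[0]) - (gx - ub[0]) * (vb[1] - vb[0])) / d
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        depth = w0 * tri_z[f, 0] + w1 * tri_z[f, 1] + w2 * tri_z[f, 2]
        sub_z = zbuf[y0 : y1 + 1, x0 : x1 + 1]
        upd = inside & (depth < sub_z)
        if not upd.any():
            continue
        sub_z[upd] = depth[upd]
        color = np.clip(face_albedo[f] * intensity[f], 0.0, 1.0)
        image[y0 : y1 + 1, x0 : x1 + 1][upd] = color

    if blur_px > 0:
        image = _motion_blur(image, blur_px, float(rng.uniform(0, np.pi)))

    landmarks = project(mesh.vertices[subset], pose, cam)
    ui = np.clip(np.round(landmarks.points[:, 0]).astype(int), 0, w - 1)
    vi = np.clip(np.round(landmarks.points[:, 1]).astype(int), 0, h - 1)
    zl = z[subset]
    visible = (landmarks.in_bounds) & (zl <= zbuf[vi, ui] + 0.02 * zl)

    return SyntheticSample(
        image=image,
        landmarks=landmarks,
        visible=visible,
        pose=pose,
        cam=cam,
        mesh_id=mesh_id,
        seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def make_dataset(
    meshes: Sequence[TriMesh],
    out_dir,
    topology: TemplateTopology,
    images_per_mesh: int = 100,
    cam: Optional[CameraIntrinsics] = None,
    seed: int = 0,
    rot_range_deg: float = 20.0,
    dist_jitter: float = 0.15,
    max_blur_px: float = 2.0,
) -> dict:
    """Render a seeded augmented dataset and write it to disk.

    Layout: ``images/*.png``, ``landmarks/*.json`` and a ``manifest.json``
    listing image path, landmark path, mesh id and per-sample seed.
    """
    import imageio.v3 as iio

    if len(meshes) < 1:
        raise InvalidParameterError("need at least one mesh")
    if cam is None:
        cam = approximate_intrinsics(256, 256)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)

    entries = []
    for mi, mesh in enumerate(meshes):
        for ii in range(images_per_mesh):
            rng = np.random.default_rng([seed, mi, ii])
            sample_seed = int(rng.integers(2 ** 31))
            pose = random_pose(mesh, cam, rng, rot_range_deg, dist_jitter)
            blur = float(rng.uniform(0.0, max_blur_px))
            light = rng.normal(size=3)
            light[2] = abs(light[2]) + 1.0
            sample = render(
                mesh, pose, cam, topology=topology, light_dir=light,
                blur_px=blur, rng_seed=sample_seed, mesh_id=mi,
            )
            img_rel = f"images/m{mi:03d}_i{ii:03d}.png"
            lm_rel = f"landmarks/m{mi:03d}_i{ii:03d}.json"
            iio.imwrite(out / img_rel, (sample.image * 255).round().astype(np.uint8))
            (out / lm_rel).write_text(json.dumps({
                "points": sample.landmarks.points.tolist(),
                "visible": sample.visible.tolist(),
                "width": cam.width,
                "height": cam.height,
                "image": img_rel,
            }))
            entries.append({
                "image": img_rel,
                "landmarks": lm_rel,
                "mesh_id": mi,
                "seed": sample_seed,
            })
    manifest = {
        "n_meshes": len(meshes),
        "images_per_mesh": images_per_mesh,
        "seed": seed,
        "n_landmarks": int(len(topology.landmark_subset) or meshes[0].n_vertices),
        "samples": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
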