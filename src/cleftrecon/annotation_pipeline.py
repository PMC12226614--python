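"""Dense video annotation: track, transfer, reproject, filter.

Given one sparsely annotated frame of an intraoral video, the pipeline
propagates the sparse 2D landmarks through the video by patch tracking,
maps the annotated 3D points onto the template mesh, estimates a per-frame
similarity pose from the sparse tracks, and reprojects every template vertex
to obtain dense annotations. Frames are then filtered on the number of
in-bounds points, the reprojection error, and jumps of the projection matrix
between neighboring frames.

The baseline tracker is normalized cross-correlation patch matching run
forward and backward from the annotated frame; any long-term pixel tracker
with the same call contract can be plugged in instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import match_template

from .core_geometry import (
    CameraIntrinsics,
    CorrespondenceSet,
    Landmarks2D,
    SimilarityPose,
    TriMesh,
    estimate_pose,
    project,
)
from .exceptions import CleftReconError, InvalidParameterError

__all__ = [
    "VideoFrames",
    "TrackedLandmarks",
    "QualityReport",
    "FilterThresholds",
    "DensifyResult",
    "track_landmarks",
    "transfer_landmarks",
    "densify",
    "quality_filter",
    "write_quality_report",
    "load_video_frames",
]


@dataclass
class VideoFrames:
    """An ordered stack of equally sized RGB frames."""

    frames: np.ndarray            # (T, H, W, 3) in [0, 1]
    frame_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or len(self.frames) < 1:
            raise InvalidParameterError("frames must be a non-empty (T, H, W, 3) stack")
        if self.frame_ids is None:
            self.frame_ids = list(range(len(self.frames)))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackedLandmarks:
    """Per-frame landmark positions with a validity (not-lost) mask."""

    points: np.ndarray            # (T, L, 2)
    valid: np.ndarray             # (T, L) bool; False = track lost

    def landmarks(self, t: int) -> Landmarks2D:
        return Landmarks2D(self.points[t], in_bounds=self.valid[t])


@dataclass
class QualityReport:
    frame_id: object
    n_in_bounds: int
    reproj_rmse: float
    pose_change: float
    accepted: bool


@dataclass
class FilterThresholds:
    """Frame acceptance thresholds for :func:`quality_filter`."""

    min_in_bounds_frac: float = 0.9
    max_rmse: float = 3.0
    max_jump: float = 0.1


@dataclass
class DensifyResult:
    """Dense per-frame annotations and poses; None where a frame was skipped."""

    dense: List[Optional[Landmarks2D]]
    poses: List[Optional[SimilarityPose]]
    skipped: List[int] = field(default_factory=list)


def _to_gray(frame: np.ndarray) -> np.ndarray:
    return frame.mean(axis=2) if frame.ndim == 3 else frame


def _ncc_step_anchored(
    tmpl_gray: np.ndarray,
    target_gray: np.ndarray,
    tmpl_pos: np.ndarray,
    search_pos: np.ndarray,
    patch: int,
    radius: int,
):
    """Locate the template around ``tmpl_pos`` (in the template frame) inside
    a search window around ``search_pos`` (in the target frame); returns
    (position in target frame, peak correlation)."""
    h, w = tmpl_gray.shape
    half = patch // 2
    ui, vi = int(round(tmpl_pos[0])), int(round(tmpl_pos[1]))
    if not (half <= ui < w - half and half <= vi < h - half):
        return search_pos, -1.0
    tmpl = tmpl_gray[vi - half : vi + half + 1, ui - half : ui + half + 1]
    if tmpl.std() < 1e-12:
        return search_pos, -1.0
    si, sj = int(round(search_pos[0])), int(round(search_pos[1]))
    y0 = max(sj - half - radius, 0)
    y1 = min(sj + half + radius + 1, h)
    x0 = max(si - half - radius, 0)
    x1 = min(si + half + radius + 1, w)
    window = target_gray[y0:y1, x0:x1]
    if window.shape[0] < patch or window.shape[1] < patch:
        return search_pos, -1.0
    corr = match_template(window, tmpl)
    if not np.isfinite(corr).all():
        corr = np.nan_to_num(corr, nan=-1.0)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[iy, ix])
    # parabolic sub-pixel refinement along each axis; skipped at a (near-)
    # perfect match, where asymmetric texture would bias the vertex estimate
    dy = dx = 0.0
    if peak < 1.0 - 1e-9:
        if 0 < iy < corr.shape[0] - 1:
            a, b, c = corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix]
            den = a - 2 * b + c
            if abs(den) > 1e-12:
                dy = float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
        if 0 < ix < corr.shape[1] - 1:
            a, b, c = corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1]
            den = a - 2 * b + c
            if abs(den) > 1e-12:
                dx = float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
    # the template center sits at the rounded annotated position; carry the
    # fractional offset so sub-pixel localization is preserved
    new_u = x0 + ix + dx + half + (tmpl_pos[0] - ui)
    new_v = y0 + iy + dy + half + (tmpl_pos[1] - vi)
    return np.array([new_u, new_v]), peak


def track_landmarks(
    video: VideoFrames,
    init: Landmarks2D,
    frame_index: int = 0,
    tracker: Optional[Callable] = None,
    patch: int = 21,
    radius: int = 20,
    corr_threshold: float = 0.6,
) -> TrackedLandmarks:
    """Propagate sparse landmarks through the video from an annotated frame.

    The default tracker matches a patch around each landmark between
    consecutive frames (forward and backward from ``frame_index``) using
    normalized cross-correlation. Tracks whose peak correlation drops below
    ``corr_threshold`` are flagged lost and frozen, never fabricated.

    A custom ``tracker(prev_frame, next_frame, points) -> (points, scores)``
    conforming to the same contract replaces the NCC step.
    """
    t_total, h, w = video.frames.shape[:3]
    if not (0 <= frame_index < t_total):
        raise InvalidParameterError("frame_index out of range")
    pts0 = init.points
    if np.any(pts0[:, 0] < 0) or np.any(pts0[:, 0] > w - 1) or np.any(
        pts0[:, 1] < 0
    ) or np.any(pts0[:, 1] > h - 1):
        raise InvalidParameterError("initial landmarks must lie inside the frame")

    n = len(pts0)
    points = np.zeros((t_total, n, 2))
    valid = np.zeros((t_total, n), dtype=bool)
    points[frame_index] = pts0
    valid[frame_index] = True

    grays = [_to_gray(f) for f in video.frames]

    def step_all(src_t: int, dst_t: int, cur: np.ndarray, cur_valid: np.ndarray):
        """Advance all tracks one frame. The default matcher is long-term: the
        template is always taken around the landmark in the annotated frame
        (drift does not accumulate); only the search window follows the
        previous position."""
        new = cur.copy()
        ok = cur_valid.copy()
        if tracker is not None:
            tracked, scores = tracker(video.frames[src_t], video.frames[dst_t], cur)
            for i in range(n):
                if not cur_valid[i]:
                    continue
                if scores[i] < corr_threshold:
                    ok[i] = False
                else:
                    new[i] = tracked[i]
            return new, ok
        for i in range(n):
            if not cur_valid[i]:
                continue
            # template anchored at the annotated frame, window at the current track
            p, score = _ncc_step_anchored(
                grays[frame_index], grays[dst_t], pts0[i], cur[i], patch, radius
            )
            if score < corr_threshold:
                ok[i] = False
            else:
                new[i] = p
        return new, ok

    cur, cur_valid = pts0.copy(), np.ones(n, dtype=bool)
    for t in range(frame_index + 1, t_total):
        cur, cur_valid = step_all(t - 1, t, cur, cur_valid)
        points[t], valid[t] = cur, cur_valid
    cur, cur_valid = pts0.copy(), np.ones(n, dtype=bool)
    for t in range(frame_index - 1, -1, -1):
        cur, cur_valid = step_all(t + 1, t, cur, cur_valid)
        points[t], valid[t] = cur, cur_valid
    return TrackedLandmarks(points, valid)


def transfer_landmarks(
    original_mesh: TriMesh,
    annotated_points: np.ndarray,
    registered_template: TriMesh,
) -> np.ndarray:
    """Map annotated 3D points on the original scan to template vertex ids.

    Each point maps to its nearest template vertex (Euclidean); exact distance
    ties break to the lower vertex index, and duplicates resolve to the next
    nearest free vertex.
    """
    pts = np.asarray(annotated_points, dtype=np.float64).reshape(-1, 3)
    verts = registered_template.vertices
    tree = cKDTree(verts)
    k = min(len(verts), max(8, len(pts) + 1))
    dists, idxs = tree.query(pts, k=k)
    dists, idxs = np.atleast_2d(dists), np.atleast_2d(idxs)
    # enforce the lower-index tie-break within each candidate list
    order = np.lexsort((idxs, np.round(dists / 1e-12).astype(np.int64)), axis=1)
    result = np.full(len(pts), -1, dtype=np.int64)
    taken: set = set()
    for i in range(len(pts)):
        for j in order[i]:
            cand = int(idxs[i, j])
            if cand not in taken:
                result[i] = cand
                taken.add(cand)
                break
        if result[i] < 0:
            # all k candidates taken; brute-force over the remainder
            free = np.setdiff1d(np.arange(len(verts)), np.fromiter(taken, dtype=np.int64))
            d = np.linalg.norm(verts[free] - pts[i], axis=1)
            result[i] = int(free[np.argmin(d)])
            taken.add(int(result[i]))
    return result


def densify(
    video: VideoFrames,
    sparse_tracks: TrackedLandmarks,
    vertex_ids: np.ndarray,
    template: TriMesh,
    cam: CameraIntrinsics,
) -> DensifyResult:
    """Per-frame dense reprojection of all template vertices.

    For every frame with at least 4 unlost sparse tracks, the similarity pose
    is estimated from the tracked correspondences (warm-started from the
    previous frame's pose) and all template vertices are projected. Frames
    with fewer usable tracks, or a failed pose fit, are skipped and reported.
    """
    vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
    t_total = len(video)
    dense: List[Optional[Landmarks2D]] = [None] * t_total
    poses: List[Optional[SimilarityPose]] = [None] * t_total
    skipped: List[int] = []
    prev_pose: Optional[SimilarityPose] = None
    for t in range(t_total):
        ok = sparse_tracks.valid[t]
        if ok.sum() < 4:
            skipped.append(t)
            continue
        corr = CorrespondenceSet(vertex_ids[ok], sparse_tracks.points[t][ok])
        try:
            pose = estimate_pose(
                corr, template.vertices, cam,
                init=prev_pose, multistart=prev_pose is None,
            )
            dense[t] = project(template.vertices, pose, cam)
        except CleftReconError:
            skipped.append(t)
            continue
        poses[t] = pose
        prev_pose = pose
    return DensifyResult(dense, poses, skipped)


def pose_change_metric(
    pose_a: SimilarityPose, pose_b: SimilarityPose, cam: CameraIntrinsics
) -> float:
    """Frobenius distance of the Frobenius-normalized 3x4 projection matrices.

    Normalizing each K [sR | T] by its own norm makes the metric
    dimensionless (rotation and mm-scale translation entries would otherwise
    mix units) and invariant to the projectively invisible (s, T) -> (ks, kT)
    scale gauge.
    """
    ma = pose_a.projection_matrix(cam)
    mb = pose_b.projection_matrix(cam)
    ma = ma / np.linalg.norm(ma)
    mb = mb / np.linalg.norm(mb)
    return float(np.linalg.norm(ma - mb))


def quality_filter(
    dense: Sequence[Optional[Landmarks2D]],
    poses: Sequence[Optional[SimilarityPose]],
    cam: CameraIntrinsics,
    tracks: Optional[TrackedLandmarks] = None,
    vertex_ids: Optional[np.ndarray] = None,
    template: Optional[TriMesh] = None,
    thresholds: FilterThresholds = FilterThresholds(),
    frame_ids: Optional[Sequence] = None,
) -> List[QualityReport]:
    """Accept or reject frames on in-bounds count, reprojection RMSE and pose jumps.

    A frame is accepted iff its in-bounds fraction is at least
    ``min_in_bounds_frac``, its sparse-track reprojection RMSE (0 when no
    tracks are supplied) is at most ``max_rmse``, and the projection-matrix
    change versus the previous annotated frame is at most ``max_jump``
    (defined as 0 for the first frame).
    """
    if len(dense) != len(poses):
        raise InvalidParameterError("dense annotations and poses must align per frame")
    if frame_ids is None:
        frame_ids = list(range(len(dense)))
    reports: List[QualityReport] = []
    prev_pose: Optional[SimilarityPose] = None
    for t, (lm, pose) in enumerate(zip(dense, poses)):
        if lm is None or pose is None:
            reports.append(QualityReport(frame_ids[t], 0, np.inf, np.inf, False))
            continue
        in_b = lm.in_bounds if lm.in_bounds is not None else np.ones(len(lm), bool)
        n_in = int(in_b.sum())
        rmse = 0.0
        if tracks is not None and vertex_ids is not None and template is not None:
            ok = tracks.valid[t]
            if ok.any():
                proj = project(template.vertices[np.asarray(vertex_ids)[ok]], pose, cam)
                res = proj.points - tracks.points[t][ok]
                rmse = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
        jump = 0.0 if prev_pose is None else pose_change_metric(prev_pose, pose, cam)
        accepted = (
            n_in >= thresholds.min_in_bounds_frac * len(lm)
            and rmse <= thresholds.max_rmse
            and jump <= thresholds.max_jump
        )
        reports.append(QualityReport(frame_ids[t], n_in, rmse, jump, bool(accepted)))
        prev_pose = pose
    return reports


def write_quality_report(reports: Sequence[QualityReport], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_id", "n_in_bounds", "reproj_rmse", "pose_change", "accepted"])
        for r in reports:
            w.writerow([r.frame_id, r.n_in_bounds, f"{r.reproj_rmse:.6g}",
                        f"{r.pose_change:.6g}", int(r.accepted)])


def load_video_frames(directory) -> VideoFrames:
    """Load a directory of numbered PNG frames as a video."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise InvalidParameterError(f"no PNG frames in {directory}")
    frames = np.stack([iio.imread(p).astype(np.float64)[:, :, :3] / 255.0 for p in paths])
    return VideoFrames(frames, [p.stem for p in paths])
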