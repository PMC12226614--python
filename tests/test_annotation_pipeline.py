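"""Dense video annotation: tracking, transfer, densification, quality filtering."""

import numpy as np
import pytest

from cleftrecon.annotation_pipeline import (
    FilterThresholds,
    QualityReport,
    TrackedLandmarks,
    VideoFrames,
    densify,
    pose_change_metric,
    quality_filter,
    track_landmarks,
    transfer_landmarks,
    write_quality_report,
)
from cleftrecon.core_geometry import (
    Landmarks2D,
    SimilarityPose,
    TriMesh,
    approximate_intrinsics,
    project,
)
from cleftrecon.synthetic_data import canonical_pose, render, synthetic_family
from scipy.spatial.transform import Rotation


@pytest.fixture(scope="module")
def rendered_video():
    """A 12-frame synthetic video of a palate under slow camera rotation,
    with ground-truth dense projections per frame."""
    topo, meshes, _ = synthetic_family(1, seed=20, nx=20, ny=20, n_landmarks=40)
    mesh = meshes[0]
    cam = approximate_intrinsics(128, 128)
    base = canonical_pose(mesh, cam)
    frames, poses = [], []
    for t in range(12):
        dr = Rotation.from_euler("xyz", [0.8 * t, -0.5 * t, 0.3 * t], degrees=True).as_matrix()
        rot = dr @ base.rotation
        d = (base.rotation @ mesh.centroid + base.translation)[2]
        trans = np.array([0.0, 0.0, d]) - rot @ mesh.centroid
        pose = SimilarityPose(rot, trans, 1.0)
        sample = render(mesh, pose, cam, topology=topo, rng_seed=77)
        frames.append(sample.image)
        poses.append(pose)
    video = VideoFrames(np.stack(frames))
    return {"video": video, "poses": poses, "mesh": mesh, "cam": cam, "topo": topo}


class TestTrackLandmarks:
    def test_static_video_returns_init_exactly(self, rendered_video):
        frame = rendered_video["video"].frames[0]
        video = VideoFrames(np.stack([frame] * 5))
        init = Landmarks2D(np.array([[40.0, 50.0], [70.0, 60.0], [55.0, 75.0]]))
        tracks = track_landmarks(video, init, frame_index=2)
        assert tracks.valid.all()
        for t in range(5):
            assert np.allclose(tracks.points[t], init.points, atol=1e-9)

    def test_smooth_motion_tracked_within_2px(self, rendered_video):
        rv = rendered_video
        ids = rv["topo"].landmark_subset[::4]
        gt0 = project(rv["mesh"].vertices[ids], rv["poses"][0], rv["cam"])
        keep = gt0.in_bounds
        init = Landmarks2D(gt0.points[keep])
        tracks = track_landmarks(rv["video"], init, frame_index=0)
        errs = []
        for t in range(len(rv["video"])):
            gt = project(rv["mesh"].vertices[ids[keep]], rv["poses"][t], rv["cam"]).points
            ok = tracks.valid[t]
            if ok.any():
                errs.append(np.sqrt(np.mean(np.sum((tracks.points[t][ok] - gt[ok]) ** 2, axis=1))))
        assert tracks.valid[-1].mean() > 0.6  # most tracks survive
        assert np.max(errs) < 2.0

    def test_featureless_background_flagged_lost(self):
        video = VideoFrames(np.zeros((3, 64, 64, 3)))
        init = Landmarks2D(np.array([[32.0, 32.0]]))
        tracks = track_landmarks(video, init, frame_index=0)
        assert tracks.valid[0, 0]          # the annotated frame itself
        assert not tracks.valid[1, 0]      # lost immediately, not fabricated
        assert not tracks.valid[2, 0]

    def test_pluggable_tracker_contract(self, rendered_video):
        frame = rendered_video["video"].frames[0]
        video = VideoFrames(np.stack([frame] * 3))
        init = Landmarks2D(np.array([[40.0, 50.0]]))

        def shifting_tracker(prev, nxt, pts):
            return pts + [1.0, 0.0], np.ones(len(pts))

        tracks = track_landmarks(video, init, frame_index=0, tracker=shifting_tracker)
        assert np.allclose(tracks.points[2, 0], [42.0, 50.0])


class TestTransferLandmarks:
    def test_exact_vertex_maps_to_itself(self, small_family):
        _, meshes, _ = small_family
        template = meshes[0]
        pts = template.vertices[[5, 100, 400]]
        ids = transfer_landmarks(template, pts, template)
        assert ids.tolist() == [5, 100, 400]

    def test_equidistant_tie_breaks_to_lower_index(self):
        verts = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 5, 0], [1.0, -5, 0]])
        faces = np.array([[0, 1, 2], [0, 1, 3]])
        template = TriMesh(verts, faces)
        ids = transfer_landmarks(template, np.array([[1.0, 0.0, 0.0]]), template)
        assert ids[0] == 0

    def test_duplicates_resolve_to_next_nearest(self):
        verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0]])
        faces = np.array([[0, 1, 2], [0, 1, 3]])
        template = TriMesh(verts, faces)
        pts = np.array([[0.1, 0, 0], [0.2, 0, 0]])
        ids = transfer_landmarks(template, pts, template)
        assert ids[0] == 0 and ids[1] == 1

    def test_matches_bruteforce_nearest_within_edge_length(self, small_family):
        _, meshes, _ = small_family
        template = meshes[1]
        rng = np.random.default_rng(4)
        # random points near the surface
        idx = rng.integers(0, template.n_vertices, 25)
        pts = template.vertices[idx] + rng.normal(0, 0.2, (25, 3))
        ids = transfer_landmarks(template, pts, template)
        edges = template.vertices[template.faces[:, 0]] - template.vertices[template.faces[:, 1]]
        max_edge = np.linalg.norm(edges, axis=1).max()
        brute = np.array([
            np.argmin(np.linalg.norm(template.vertices - p, axis=1)) for p in pts
        ])
        dist = np.linalg.norm(template.vertices[ids] - pts, axis=1)
        brute_dist = np.linalg.norm(template.vertices[brute] - pts, axis=1)
        # duplicates may fall back to next-nearest; all stay within an edge length
        assert np.all(dist <= brute_dist + max_edge)
        assert np.all(dist <= max_edge + 0.6)


class TestDensify:
    def _exact_tracks(self, rv, n_sparse=12):
        ids = rv["topo"].landmark_subset[:: max(1, len(rv["topo"].landmark_subset) // n_sparse)]
        points = np.stack([
            project(rv["mesh"].vertices[ids], pose, rv["cam"]).points
            for pose in rv["poses"]
        ])
        valid = np.ones(points.shape[:2], dtype=bool)
        return ids, TrackedLandmarks(points, valid)

    def test_dense_matches_ground_truth(self, rendered_video):
        rv = rendered_video
        ids, tracks = self._exact_tracks(rv)
        result = densify(rv["video"], tracks, ids, rv["mesh"], rv["cam"])
        assert not result.skipped
        for t, lm in enumerate(result.dense):
            assert len(lm) == rv["mesh"].n_vertices
            gt = project(rv["mesh"].vertices, rv["poses"][t], rv["cam"]).points
            rms = np.sqrt(np.mean(np.sum((lm.points - gt) ** 2, axis=1)))
            assert rms < 0.5

    def test_reprojection_fixed_point(self, rendered_video):
        """Re-estimating pose from densify's own output reproduces the same
        projections."""
        from cleftrecon.core_geometry import CorrespondenceSet, estimate_pose

        rv = rendered_video
        ids, tracks = self._exact_tracks(rv)
        result = densify(rv["video"], tracks, ids, rv["mesh"], rv["cam"])
        lm = result.dense[3]
        pose = result.poses[3]
        sub = np.arange(0, rv["mesh"].n_vertices, 23)
        re_pose = estimate_pose(
            CorrespondenceSet(sub, lm.points[sub]), rv["mesh"].vertices, rv["cam"],
            init=pose,
        )
        re_proj = project(rv["mesh"].vertices, re_pose, rv["cam"]).points
        assert np.allclose(re_proj, lm.points, atol=1e-6)

    def test_frames_with_too_few_tracks_skipped(self, rendered_video):
        rv = rendered_video
        ids, tracks = self._exact_tracks(rv)
        tracks.valid[5, 3:] = False  # leave only 3 valid tracks in frame 5
        result = densify(rv["video"], tracks, ids, rv["mesh"], rv["cam"])
        assert result.skipped == [5]
        assert result.dense[5] is None


class TestQualityFilter:
    def _static_inputs(self, n=6, n_pts=20):
        cam = approximate_intrinsics(100, 100)
        pose = SimilarityPose(np.eye(3), np.array([0, 0, 200.0]), 1.0)
        lm = Landmarks2D(np.full((n_pts, 2), 50.0), in_bounds=np.ones(n_pts, bool))
        return [lm] * n, [pose] * n, cam

    def test_clean_static_sequence_all_accepted(self):
        dense, poses, cam = self._static_inputs()
        reports = quality_filter(dense, poses, cam)
        assert all(r.accepted for r in reports)
        assert reports[0].pose_change == 0.0

    def test_teleported_pose_rejected_exactly(self):
        dense, poses, cam = self._static_inputs()
        poses = list(poses)
        far = SimilarityPose(
            Rotation.from_euler("z", 60, degrees=True).as_matrix(),
            np.array([50.0, 0, 400.0]), 1.0,
        )
        poses[3] = far
        reports = quality_filter(dense, poses, cam)
        rejected = [r.frame_id for r in reports if not r.accepted]
        # the jump is charged to the teleported frame and to the return frame
        assert 3 in rejected and all(f in (3, 4) for f in rejected)

    def test_zero_rmse_threshold_keeps_only_exact_frames(self, rendered_video):
        rv = rendered_video
        ids = rv["topo"].landmark_subset[::4]
        points = np.stack([
            project(rv["mesh"].vertices[ids], pose, rv["cam"]).points
            for pose in rv["poses"]
        ])
        noisy = points.copy()
        noisy[1:] += 1.0  # every frame except 0 gets biased tracks
        tracks = TrackedLandmarks(noisy, np.ones(points.shape[:2], bool))
        dense = [project(rv["mesh"].vertices, p, rv["cam"]) for p in rv["poses"]]
        reports = quality_filter(
            dense, rv["poses"], rv["cam"], tracks=tracks, vertex_ids=ids,
            template=rv["mesh"],
            thresholds=FilterThresholds(max_rmse=1e-9, max_jump=np.inf,
                                        min_in_bounds_frac=0.0),
        )
        assert [r.accepted for r in reports] == [True] + [False] * 11

    def test_survivors_monotone_under_tightening(self, rendered_video):
        rv = rendered_video
        dense = [project(rv["mesh"].vertices, p, rv["cam"]) for p in rv["poses"]]
        prev = None
        for jump in (1.0, 0.1, 0.01, 0.001, 0.0):
            reports = quality_filter(
                dense, rv["poses"], rv["cam"],
                thresholds=FilterThresholds(max_jump=jump),
            )
            n = sum(r.accepted for r in reports)
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for frac in (0.0, 0.5, 0.9, 0.99, 1.01):
            reports = quality_filter(
                dense, rv["poses"], rv["cam"],
                thresholds=FilterThresholds(min_in_bounds_frac=frac, max_jump=np.inf),
            )
            n = sum(r.accepted for r in reports)
            if prev is not None:
                assert n <= prev
            prev = n

    def test_report_csv(self, tmp_path):
        reports = [QualityReport(0, 10, 0.5, 0.0, True), QualityReport(1, 2, 9.0, 0.2, False)]
        path = tmp_path / "quality_report.csv"
        write_quality_report(reports, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "frame_id,n_in_bounds,reproj_rmse,pose_change,accepted"
        assert len(lines) == 3


class TestEndToEnd:
    def test_thirty_frame_video_fully_accepted_with_exact_tracks(self):
        """With exact tracks and default thresholds every frame survives."""
        topo, meshes, _ = synthetic_family(1, seed=21, nx=16, ny=16, n_landmarks=30)
        mesh = meshes[0]
        cam = approximate_intrinsics(96, 96)
        base = canonical_pose(mesh, cam)
        poses = []
        for t in range(30):
            dr = Rotation.from_euler("y", 0.4 * t, degrees=True).as_matrix()
            rot = dr @ base.rotation
            d = (base.rotation @ mesh.centroid + base.translation)[2]
            poses.append(SimilarityPose(rot, np.array([0, 0, d]) - rot @ mesh.centroid, 1.0))
        video = VideoFrames(np.zeros((30, 96, 96, 3)))
        ids = topo.landmark_subset[::2]
        points = np.stack([project(mesh.vertices[ids], p, cam).points for p in poses])
        tracks = TrackedLandmarks(points, np.ones(points.shape[:2], bool))
        result = densify(video, tracks, ids, mesh, cam)
        reports = quality_filter(
            result.dense, result.poses, cam, tracks=tracks, vertex_ids=ids,
            template=mesh,
        )
        assert sum(r.accepted for r in reports) == 30
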