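"""PCA shape model: construction, truncation, encoding, sampling, errors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cleftrecon.core_geometry import TriMesh
from cleftrecon.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    TopologyError,
)
from cleftrecon.shape_model import (
    ShapeCoefficients,
    ShapeModel,
    align_to_model,
    build_pca,
    load_model,
    project_to_model,
    reconstruct,
    reconstruction_error,
    sample_coefficients,
    save_model,
)
from cleftrecon.synthetic_data import PalateParams, generate_palate


class TestBuildPCA:
    def test_two_meshes_give_one_full_variance_mode(self, small_family):
        _, meshes, _ = small_family
        model = build_pca(meshes[:2], 0.999)
        assert model.n_modes == 1

    def test_matches_bruteforce_gram_eigendecomposition(self, small_family):
        """Retained eigen-pairs equal a brute-force covariance eigendecomposition."""
        _, meshes, _ = small_family
        sub = meshes[:20]
        model = build_pca(sub, 0.999, align=False)
        x = np.stack([m.vertices.reshape(-1) for m in sub])
        xc = x - x.mean(axis=0)
        # Gram trick: eigenvectors of (1/(n-1)) X X^T map to covariance modes
        gram = xc @ xc.T / (len(x) - 1)
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = model.n_modes
        assert np.allclose(model.variances, evals[:k], rtol=1e-6)
        modes = (xc.T @ evecs[:, :k])
        modes /= np.linalg.norm(modes, axis=0)
        for i in range(k):
            dot = abs(float(modes[:, i] @ model.components[i]))
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_threshold_one_retains_full_rank(self, small_family):
        _, meshes, _ = small_family
        n = 12
        model = build_pca(meshes[:n], 1.0)
        assert model.n_modes == n - 1

    def test_cumulative_variance_reaches_threshold(self, small_model, small_family):
        _, meshes, _ = small_family
        from cleftrecon.shape_model import generalized_procrustes

        verts = generalized_procrustes([m.vertices for m in meshes])
        x = np.stack([v.reshape(-1) for v in verts])
        xc = x - x.mean(axis=0)
        total = (xc ** 2).sum() / (len(x) - 1)
        assert small_model.variances.sum() / total >= 0.999

    def test_fewer_than_two_meshes_rejected(self, small_family):
        _, meshes, _ = small_family
        with pytest.raises(InsufficientDataError):
            build_pca(meshes[:1])

    def test_mismatched_vertex_counts_rejected(self, small_family):
        _, meshes, _ = small_family
        other = generate_palate(PalateParams(), nx=10, ny=10)
        with pytest.raises(TopologyError):
            build_pca([meshes[0], other])

    def test_rigid_transform_invariance_of_variances(self, small_family):
        """Procrustes pre-alignment: rotating every input identically leaves
        the retained variances unchanged to 1e-6 relative."""
        _, meshes, _ = small_family
        sub = meshes[:10]
        rot = Rotation.from_euler("xyz", [25, -40, 65], degrees=True).as_matrix()
        shift = np.array([10.0, -7.0, 3.0])
        moved = [TriMesh(m.vertices @ rot.T + shift, m.faces) for m in sub]
        v0 = build_pca(sub, 0.999).variances
        v1 = build_pca(moved, 0.999).variances
        assert len(v0) == len(v1)
        assert np.allclose(v0, v1, rtol=1e-6)


class TestReconstructAndEncode:
    def test_zero_coefficients_give_mean(self, small_model):
        rec = reconstruct(small_model, np.zeros(small_model.n_modes))
        assert np.allclose(rec.vertices.reshape(-1), small_model.mean_shape)

    def test_unit_weight_is_additive(self, small_model):
        w = np.zeros(small_model.n_modes)
        w[0] = 1.0
        rec = reconstruct(small_model, w)
        expected = small_model.mean_shape + small_model.components[0]
        assert np.allclose(rec.vertices.reshape(-1), expected)

    def test_training_mesh_roundtrip_full_rank(self, small_family):
        _, meshes, _ = small_family
        sub = meshes[:12]
        model = build_pca(sub, 1.0)
        aligned = align_to_model(model, sub[3])
        rec = reconstruct(model, project_to_model(model, aligned))
        rms = np.sqrt(np.mean(np.sum((rec.vertices - aligned.vertices) ** 2, axis=1)))
        assert rms < 1e-6

    def test_mean_mesh_encodes_to_zero(self, small_model):
        coeffs = project_to_model(small_model, small_model.mean_mesh())
        assert np.allclose(coeffs.weights, 0.0, atol=1e-10)

    def test_mode_displacement_encodes_exactly(self, small_model):
        flat = small_model.mean_shape + 2.0 * small_model.components[3]
        mesh = TriMesh(flat.reshape(-1, 3), small_model.topology.faces)
        w = project_to_model(small_model, mesh).weights
        expected = np.zeros(small_model.n_modes)
        expected[3] = 2.0
        assert np.allclose(w, expected, atol=1e-8)

    def test_residual_orthogonal_to_components(self, small_model):
        rng = np.random.default_rng(9)
        flat = small_model.mean_shape + rng.normal(0, 1.0, len(small_model.mean_shape))
        mesh = TriMesh(flat.reshape(-1, 3), small_model.topology.faces)
        rec = reconstruct(small_model, project_to_model(small_model, mesh))
        residual = mesh.vertices.reshape(-1) - rec.vertices.reshape(-1)
        dots = small_model.components @ residual
        assert np.abs(dots).max() < 1e-6

    def test_wrong_coefficient_length_rejected(self, small_model):
        with pytest.raises(InvalidParameterError):
            reconstruct(small_model, np.zeros(small_model.n_modes + 1))


class TestSampleCoefficients:
    def test_deterministic_given_seed(self, small_model):
        a = sample_coefficients(small_model, 42).weights
        b = sample_coefficients(small_model, 42).weights
        assert np.array_equal(a, b)

    def test_sample_variance_matches_model(self, small_model):
        rng = np.random.default_rng(7)
        draws = np.stack([sample_coefficients(small_model, rng).weights for _ in range(10000)])
        sample_var = draws.var(axis=0)
        assert np.allclose(sample_var, small_model.variances, rtol=0.05)

    def test_zero_variance_mode_stays_zero(self, small_model):
        topo = small_model.topology
        model = ShapeModel(
            small_model.mean_shape,
            small_model.components[:2],
            np.array([4.0, 0.0]),
            topo,
            n_training=3,
        )
        for seed in range(5):
            w = sample_coefficients(model, seed).weights
            assert w[1] == 0.0


class TestReconstructionError:
    def test_training_mesh_error_negligible_full_rank(self, small_family):
        _, meshes, _ = small_family
        model = build_pca(meshes[:12], 1.0)
        err = reconstruction_error(model, meshes[5])
        assert err.mean < 1e-6

    def test_discarded_mode_error_equals_displacement(self, small_model):
        """A mesh displaced along a direction outside the retained basis keeps
        exactly that displacement as reconstruction error."""
        rng = np.random.default_rng(3)
        direction = rng.normal(size=len(small_model.mean_shape))
        direction -= small_model.components.T @ (small_model.components @ direction)
        direction /= np.linalg.norm(direction)
        flat = small_model.mean_shape + 2.5 * direction
        mesh = TriMesh(flat.reshape(-1, 3), small_model.topology.faces)
        err = reconstruction_error(small_model, mesh, align=False)
        disp = 2.5 * np.linalg.norm(direction.reshape(-1, 3), axis=1)
        assert np.allclose(err.per_vertex, disp, atol=1e-9)

    def test_single_vertex_region(self, small_model):
        mesh = small_model.mean_mesh()
        mesh.vertices[7] += [0.0, 0.0, 1.0]
        err_full = reconstruction_error(small_model, mesh, align=False)
        err_one = reconstruction_error(small_model, mesh, region=np.array([7]), align=False)
        assert err_one.per_vertex.shape == (1,)
        assert err_one.mean == pytest.approx(err_full.per_vertex[7])

    def test_empty_region_rejected(self, small_model):
        with pytest.raises(InvalidParameterError):
            reconstruction_error(small_model, small_model.mean_mesh(), region=np.array([], dtype=int))

    def test_adding_modes_never_increases_error(self, small_family):
        """Nested models: the residual norm (RMS over vertices) is monotone
        non-increasing in the number of retained modes."""
        _, meshes, _ = small_family
        full = build_pca(meshes[:16], 1.0)
        held = meshes[20]
        prev = np.inf
        for k in range(1, full.n_modes + 1):
            model_k = ShapeModel(full.mean_shape, full.components[:k],
                                 full.variances[:k], full.topology, full.n_training)
            err = reconstruction_error(model_k, held)
            rms = float(np.sqrt(np.mean(err.per_vertex ** 2)))
            assert rms <= prev + 1e-9
            prev = rms


class TestSerialization:
    def test_save_load_roundtrip(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        back = load_model(path)
        assert np.array_equal(back.mean_shape, small_model.mean_shape)
        assert np.array_equal(back.components, small_model.components)
        assert np.array_equal(back.variances, small_model.variances)
        assert np.array_equal(back.topology.landmark_subset,
                              small_model.topology.landmark_subset)
        assert back.n_training == small_model.n_training
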