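"""Shared fixtures: small seeded synthetic families and a toy trained predictor.

Session-scoped because the family, PCA model and the single-identity training
run are reused by many tests; everything is seeded and deterministic.
"""

import numpy as np
import pytest

from cleftrecon.core_geometry import approximate_intrinsics
from cleftrecon.shape_model import build_pca
from cleftrecon.synthetic_data import random_pose, render, synthetic_family


@pytest.fixture(scope="session")
def small_family():
    """30 corresponded palate meshes on a 30x30 grid with an 80-point subset."""
    topo, meshes, params = synthetic_family(30, seed=2, nx=30, ny=30, n_landmarks=80)
    return topo, meshes, params


@pytest.fixture(scope="session")
def small_model(small_family):
    topo, meshes, _ = small_family
    return build_pca(meshes, 0.999, topology=topo)


@pytest.fixture(scope="session")
def cam256():
    return approximate_intrinsics(256, 256)


@pytest.fixture(scope="session")
def cam64():
    return approximate_intrinsics(64, 64)


@pytest.fixture(scope="session")
def ceiling_run(cam64):
    """Single-identity toy training run: 1 mesh, 100 renders at 64x64, 50 landmarks."""
    from cleftrecon.landmark_predictor import PredictorConfig, train

    topo, meshes, _ = synthetic_family(1, seed=3, nx=24, ny=24, n_landmarks=50)
    samples = []
    for ri in range(100):
        rng = np.random.default_rng([3, 0, ri])
        pose = random_pose(meshes[0], cam64, rng, rot_range_deg=15.0)
        samples.append(
            render(meshes[0], pose, cam64, topology=topo,
                   rng_seed=int(rng.integers(2 ** 31)))
        )
    from cleftrecon.landmark_predictor import AugmentConfig

    # photometric augmentation spans a wide image-quality axis so the
    # predicted variance can calibrate against input degradation
    aug = AugmentConfig(rotation_deg=0.0, flip_prob=0.0, color_shift=0.08, noise_std=0.4)
    cfg = PredictorConfig(image_size=64, n_landmarks=50, epochs=60, seed=0, augment=aug)
    predictor, log = train(samples, cfg)
    return {
        "topology": topo,
        "mesh": meshes[0],
        "samples": samples,
        "predictor": predictor,
        "log": log,
        "cfg": cfg,
    }
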