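"""Uncertainty-aware 2D landmark regression.

A small strided-convolution encoder with a fully connected head predicts,
for every sub-sampled template vertex, the mean (u, v) of a Gaussian over
its image position plus a per-landmark variance. Training minimizes the
negative Gaussian log-likelihood

    L = 1/2 [ log max(sigma^2, eps) + (y - mu)^2 / max(sigma^2, eps) ]

per coordinate, which penalizes both error and miscalibrated confidence.
Landmark coordinates are normalized to [-1, 1] inside the network and
de-normalized at the interface; variance positivity is enforced with a
softplus map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import affine_transform
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from . import _nn
from .core_geometry import Landmarks2D, TemplateTopology
from .exceptions import ConvergenceError, InvalidParameterError, InsufficientDataError

__all__ = [
    "LossConfig",
    "AugmentConfig",
    "PredictorConfig",
    "LandmarkPredictor",
    "subsample_landmarks",
    "gaussian_nll",
    "augment",
    "train",
    "load_predictor",
]


# ---------------------------------------------------------------------------
# landmark sub-sampling
# ---------------------------------------------------------------------------


def subsample_landmarks(
    topology: TemplateTopology,
    n: int,
    ridge_weight: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Weighted farthest-point sub-sampling of template vertices.

    Works on graph hop distances over the template connectivity, so no vertex
    coordinates are needed. Contact-region (ridge) vertices carry
    ``ridge_weight`` times the selection density, producing a denser sample
    where the orthodontic plate touches the palate. Deterministic for a given
    seed; returns a sorted array of exactly ``n`` unique vertex indices.
    """
    if n < 1 or n > topology.n_vertices:
        raise InvalidParameterError(
            f"requested {n} landmarks from {topology.n_vertices} vertices"
        )
    if ridge_weight < 1.0:
        raise InvalidParameterError("ridge_weight must be >= 1")
    nv = topology.n_vertices
    f = topology.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    graph = coo_matrix(
        (np.ones(2 * len(edges)),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(nv, nv),
    ).tocsr()

    weight = np.ones(nv)
    weight[topology.contact_region] = float(ridge_weight)

    rng = np.random.default_rng(seed)
    start = int(rng.integers(nv))
    selected = [start]
    dist = dijkstra(graph, indices=start, unweighted=True)
    for _ in range(n - 1):
        score = weight * dist
        score[selected] = -1.0
        nxt = int(np.argmax(score))
        selected.append(nxt)
        nd = dijkstra(graph, indices=nxt, unweighted=True)
        np.minimum(dist, nd, out=dist)
    return np.sort(np.array(selected, dtype=np.int64))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


@dataclass
class LossConfig:
    """Gaussian NLL configuration: variance floor and reduction mode."""

    eps: float = float(np.finfo(np.float64).eps)
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise InvalidParameterError("eps must be positive")
        if self.reduction not in ("mean", "sum"):
            raise InvalidParameterError("reduction must be 'mean' or 'sum'")


def gaussian_nll(y, mu, sigma2, cfg: LossConfig = LossConfig()):
    """Negative Gaussian log-likelihood per coordinate, reduced per config.

    L = 1/2 [ log max(sigma^2, eps) + (y - mu)^2 / max(sigma^2, eps) ].
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma2))):
        raise InvalidParameterError("gaussian_nll inputs must be finite")
    s2 = np.maximum(sigma2, cfg.eps)
    loss = 0.5 * (np.log(s2) + (y - mu) ** 2 / s2)
    if cfg.reduction == "mean":
        return float(np.mean(loss))
    return float(np.sum(loss))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentConfig:
    """Seeded training-time augmentation ranges."""

    rotation_deg: float = 30.0
    flip_prob: float = 0.5
    color_shift: float = 0.1
    noise_std: float = 0.02
    symmetry_map: Optional[np.ndarray] = None  # landmark permutation under h-flip


def _rotate_image(image: np.ndarray, theta: float, center_uv: np.ndarray) -> np.ndarray:
    """Rotate image by theta (rad) about center, bilinear, matching the
    forward landmark map p' = R(theta) (p - c) + c in (u, v) coordinates."""
    c, s = np.cos(theta), np.sin(theta)
    # inverse map in (v, u) = (row, col) ordering
    m = np.array([[c, -s], [s, c]])
    cv = np.array([center_uv[1], center_uv[0]])
    offset = cv - m @ cv
    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        out[:, :, ch] = affine_transform(
            image[:, :, ch], m, offset=offset, order=1, mode="nearest"
        )
    return out


def augment(image: np.ndarray, landmarks, rng, cfg: AugmentConfig = AugmentConfig()):
    """Apply seeded geometric + photometric augmentation to an image/landmark pair.

    The landmark coordinates undergo the same geometric transform as the
    image. With all ranges zero (and flip_prob 0) the inputs are returned
    unchanged. Horizontal flips permute landmark ids by the configured
    left/right symmetry map when one is given.
    """
    was_lm = isinstance(landmarks, Landmarks2D)
    pts = landmarks.points if was_lm else np.asarray(landmarks, dtype=np.float64)
    identity = (
        cfg.rotation_deg == 0 and cfg.flip_prob == 0 and cfg.color_shift == 0 and cfg.noise_std == 0
    )
    if identity:
        return image, landmarks

    h, w = image.shape[:2]
    img = np.asarray(image, dtype=np.float32).copy()
    pts = pts.copy()
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    if cfg.rotation_deg > 0:
        theta = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)) * np.pi / 180.0
        img = _rotate_image(img, theta, center)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        pts = (pts - center) @ rot.T + center

    if cfg.flip_prob > 0 and rng.random() < cfg.flip_prob:
        img = img[:, ::-1].copy()
        pts[:, 0] = (w - 1) - pts[:, 0]
        if cfg.symmetry_map is not None:
            pts = pts[np.asarray(cfg.symmetry_map)]

    if cfg.color_shift > 0:
        img = img + rng.uniform(-cfg.color_shift, cfg.color_shift, size=(1, 1, img.shape[2])).astype(np.float32)
    if cfg.noise_std > 0:
        # per-sample noise level: varying image quality is what lets the
        # uncertainty head learn that degraded inputs deserve larger sigma
        level = float(rng.uniform(0.0, cfg.noise_std))
        img = img + rng.normal(0.0, level, size=img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)

    if was_lm:
        return img, Landmarks2D(pts, sigma2=landmarks.sigma2)
    return img, pts


# ---------------------------------------------------------------------------
# predictor
# ---------------------------------------------------------------------------


@dataclass
class PredictorConfig:
    """Architecture and training configuration of the landmark network."""

    image_size: int = 64
    n_landmarks: int = 1000
    conv_channels: Tuple[int, ...] = (8, 16, 32, 64)
    hidden: int = 256
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 60
    val_fraction: float = 0.15
    patience: int = 10
    augment: Optional[AugmentConfig] = None
    mask_occluded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks < 1:
            raise InvalidParameterError("n_landmarks must be >= 1")
        if self.image_size < 32:
            raise InvalidParameterError("image_size must be >= 32")


_SIGMA2_FLOOR = 1e-6


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class LandmarkPredictor:
    """Convolutional landmark regressor with per-landmark predicted variance."""

    def __init__(self, cfg: PredictorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers: List[_nn.Layer] = []
        cin = 3
        size = cfg.image_size
        for cout in cfg.conv_channels:
            layers += [_nn.Conv2d(cin, cout, rng), _nn.ReLU()]
            cin = cout
            size = (size + 1) // 2
        layers.append(_nn.Flatten())
        flat = size * size * cin
        layers += [_nn.Dense(flat, cfg.hidden, rng), _nn.ReLU(),
                   _nn.Dense(cfg.hidden, 3 * cfg.n_landmarks, rng)]
        self.net = _nn.Sequential(layers)

    # -- forward passes ----------------------------------------------------

    def _forward(self, x: np.ndarray):
        out = self.net.forward(x.astype(np.float32) - 0.5)
        n, L = len(x), self.cfg.n_landmarks
        mu = out[:, : 2 * L].reshape(n, L, 2).astype(np.float64)
        sraw = out[:, 2 * L :].astype(np.float64)
        sigma2 = _softplus(sraw) + _SIGMA2_FLOOR
        return mu, sigma2, out

    def _nll_and_grad(self, x, y_norm, mask=None):
        """Mean per-coordinate NLL with shared per-landmark variance + backprop grad."""
        mu, sigma2, out = self._forward(x)
        n, L = mu.shape[:2]
        res = mu - y_norm                                  # (n, L, 2)
        if mask is None:
            m = np.ones((n, L))
        else:
            m = mask.astype(np.float64)
        n_coords = max(2.0 * m.sum(), 1.0)
        r2 = (res ** 2).sum(axis=2)                        # (n, L)
        nll = (m * (np.log(sigma2) + 0.5 * r2 / sigma2)).sum() / n_coords
        # gradients of mean NLL
        dmu = (m[..., None] * res / sigma2[..., None]) / n_coords
        dsigma2 = m * 0.5 * (2.0 / sigma2 - r2 / sigma2 ** 2) / n_coords
        sraw = out[:, 2 * L :].astype(np.float64)
        dsraw = dsigma2 / (1.0 + np.exp(-sraw))            # d softplus
        dout = np.concatenate(
            [dmu.reshape(n, 2 * L), dsraw], axis=1
        ).astype(np.float32)
        return nll, dout

    # -- public API --------------------------------------------------------

    def predict(self, image: np.ndarray) -> Landmarks2D:
        """Landmark means and variances in the original image scale (px, px^2)."""
        if not hasattr(self, "net"):
            raise InvalidParameterError("uninitialized model")
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        h0, w0 = img.shape[:2]
        ts = self.cfg.image_size
        if (h0, w0) != (ts, ts):
            from skimage.transform import resize

            img = resize(img, (ts, ts, 3), order=1, anti_aliasing=True,
                         preserve_range=True).astype(np.float32)
        mu, sigma2, _ = self._forward(img[None])
        u = (mu[0, :, 0] + 1.0) / 2.0 * w0 - 0.5
        v = (mu[0, :, 1] + 1.0) / 2.0 * h0 - 0.5
        scale2 = ((w0 + h0) / 4.0) ** 2
        return Landmarks2D(np.column_stack([u, v]), sigma2=sigma2[0] * scale2)

    def save(self, path) -> None:
        cfg = asdict(self.cfg)
        aug = cfg.pop("augment")
        if aug is not None:
            sym = aug.pop("symmetry_map")
            aug["symmetry_map"] = None if sym is None else np.asarray(sym).tolist()
        cfg["augment"] = aug
        header = {"format": "cleftrecon-predictor", "version": 1, "config": cfg}
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params())}
        np.savez_compressed(
            str(path),
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            **arrays,
        )


def load_predictor(path) -> LandmarkPredictor:
    path = str(path)
    if not path.endswith(".npz") and Path(path + ".npz").exists():
        path = path + ".npz"
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        cfg_d = dict(header["config"])
        aug = cfg_d.pop("augment")
        if aug is not None:
            sym = aug.pop("symmetry_map")
            aug = AugmentConfig(**aug, symmetry_map=None if sym is None else np.array(sym))
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        cfg = PredictorConfig(**cfg_d, augment=aug)
        model = LandmarkPredictor(cfg)
        for i, p in enumerate(model.net.params()):
            p[...] = z[f"p{i}"]
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _coerce_samples(dataset, image_size: int):
    """Accepts a manifest path, a list of SyntheticSample-like objects, or
    (image, points[, visible]) tuples. Returns images, points, visible masks."""
    from skimage.transform import resize
    import imageio.v3 as iio

    images, points, visible = [], [], []

    def add(img, pts, vis):
        img = np.asarray(img, dtype=np.float32)
        if img.dtype.kind != "f" or img.max() > 1.5:
            img = img / 255.0
        h0, w0 = img.shape[:2]
        pts = np.asarray(pts, dtype=np.float64)
        if (h0, w0) != (image_size, image_size):
            img = resize(img, (image_size, image_size, 3), order=1,
                         anti_aliasing=True, preserve_range=True).astype(np.float32)
            pts = pts * np.array([image_size / w0, image_size / h0])
        images.append(img.astype(np.float32))
        points.append(pts)
        visible.append(np.ones(len(pts), bool) if vis is None else np.asarray(vis, bool))

    if isinstance(dataset, (str, Path)):
        manifest = json.loads(Path(dataset).read_text())
        root = Path(dataset).parent
        for entry in manifest["samples"]:
            img = iio.imread(root / entry["image"]).astype(np.float32) / 255.0
            lm = json.loads((root / entry["landmarks"]).read_text())
            add(img[:, :, :3], np.asarray(lm["points"]), lm.get("visible"))
    else:
        for item in dataset:
            if hasattr(item, "image") and hasattr(item, "landmarks"):
                add(item.image, item.landmarks.points, getattr(item, "visible", None))
            else:
                img, pts = item[0], item[1]
                vis = item[2] if len(item) > 2 else None
                pts = pts.points if isinstance(pts, Landmarks2D) else pts
                add(img, pts, vis)
    if not images:
        raise InsufficientDataError("empty training dataset")
    return np.stack(images), np.stack(points), np.stack(visible)


def _normalize_points(pts: np.ndarray, size: int) -> np.ndarray:
    return 2.0 * (pts + 0.5) / size - 1.0


def train(dataset, cfg: PredictorConfig):
    """Train the landmark predictor; returns (predictor, training log).

    ``dataset`` may be a manifest path or an in-memory list of samples. The
    log records the untrained (epoch-0) validation metrics and per-epoch
    train NLL, validation NLL and validation RMSE in pixels at the training
    resolution. Early stopping on validation NLL with the configured patience;
    the best-validation weights are restored.
    """
    images, points, visible = _coerce_samples(dataset, cfg.image_size)
    n = len(images)
    if points.shape[1] != cfg.n_landmarks:
        raise InvalidParameterError(
            f"dataset has {points.shape[1]} landmarks, config expects {cfg.n_landmarks}"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = order
    xt, yt, vt = images[train_idx], points[train_idx], visible[train_idx]
    xv, yv, vv = images[val_idx], points[val_idx], visible[val_idx]

    model = LandmarkPredictor(cfg)
    opt = _nn.Adam(model.net.params(), lr=cfg.learning_rate)
    size = cfg.image_size

    def evaluate(x, y, vis):
        if len(x) == 0:
            return np.nan, np.nan
        mu, sigma2, _ = model._forward(x)
        yn = _normalize_points(y, size)
        res = mu - yn
        mask = vis if cfg.mask_occluded else np.ones(vis.shape, bool)
        m = mask.astype(float)
        n_coords = max(2 * m.sum(), 1.0)
        r2 = (res ** 2).sum(axis=2)
        nll = float((m * (np.log(sigma2) + 0.5 * r2 / sigma2)).sum() / n_coords)
        rmse_px = float(np.sqrt((m * r2).sum() / max(m.sum(), 1.0)) * size / 2.0)
        return nll, rmse_px

    log = {"epoch": [], "train_nll": [], "val_nll": [], "val_rmse_px": []}
    v0_nll, v0_rmse = evaluate(xv if n_val else xt, yv if n_val else yt, vv if n_val else vt)
    log["initial_val_nll"] = v0_nll
    log["initial_val_rmse_px"] = v0_rmse

    best_val = np.inf
    best_params = [p.copy() for p in model.net.params()]
    stale = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(xt))
        epoch_nll, n_batches = 0.0, 0
        for i in range(0, len(xt), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            xb, yb, vb = xt[idx], yt[idx], vt[idx]
            if cfg.augment is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(xb)):
                    xb[j], yb[j] = augment(xb[j], yb[j], rng, cfg.augment)
            ybn = _normalize_points(yb, size)
            mask = vb if cfg.mask_occluded else None
            nll, dout = model._nll_and_grad(xb, ybn, mask)
            if not np.isfinite(nll):
                raise ConvergenceError(f"non-finite training loss {nll} at epoch {epoch}")
            model.net.backward(dout)
            opt.step(model.net.grads())
            epoch_nll += nll
            n_batches += 1
        val_nll, val_rmse = evaluate(xv if n_val else xt, yv if n_val else yt,
                                     vv if n_val else vt)
        log["epoch"].append(epoch)
        log["train_nll"].append(epoch_nll / max(n_batches, 1))
        log["val_nll"].append(val_nll)
        log["val_rmse_px"].append(val_rmse)
        if val_nll < best_val - 1e-9:
            best_val = val_nll
            best_params = [p.copy() for p in model.net.params()]
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    for p, b in zip(model.net.params(), best_params):
        p[...] = b
    log["best_val_nll"] = float(best_val)
    return model, log
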