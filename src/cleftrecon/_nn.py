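"""Minimal numpy neural-network layers with manual backprop.

Just enough machinery for the landmark-regression network: strided 3x3
convolutions (im2col), ReLU, dense layers and Adam. Data layout is
channels-last float32: (N, H, W, C).
"""

from __future__ import annotations

from typing import List

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Conv2d", "ReLU", "Flatten", "Dense", "Sequential", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    n, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sn, sh, sw, sc = x.strides
    cols = as_strided(
        x,
        shape=(n, ho, wo, k, k, c),
        strides=(sn, sh * stride, sw * stride, sh, sw, sc),
    )
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    n, h, w, c = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += dcols[:, :, :, i, j, :]
    if pad:
        return dxp[:, pad:-pad, pad:-pad, :]
    return dxp


class Layer:
    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = k * k * cin
        self.w = (rng.standard_normal((k * k * cin, cout)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.xshape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        self.cols = cols.reshape(n * ho * wo, -1)
        out = self.cols @ self.w + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, ho, wo, cout = dy.shape
        dyf = dy.reshape(-1, cout)
        self.dw[...] = self.cols.T @ dyf
        self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.w.T).reshape(n, ho, wo, self.k, self.k, -1)
        return _col2im(dcols, self.xshape, self.k, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self.mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self.xshape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = self.x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
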