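"""Minimal NumPy neural-network core for the convolutional VAE.

Implements exactly the layers the latent-feature model needs — 3x3
convolutions with stride 2 and "same" padding, their transposed
counterparts, dense layers, ReLU/sigmoid — with hand-derived gradients and
an RMSProp optimizer.  Convolutions are expressed as im2col + GEMM; the
transposed convolution is the exact adjoint of the forward convolution
(its forward pass is the convolution's backward-data pass), which keeps
the encoder/decoder mirror property and makes the gradient code symmetric.

Everything is deterministic given the generator passed at construction.
"""

from __future__ import annotations

import math

import numpy as np

KSIZE = 3


def _same_geometry(n: int, stride: int) -> tuple[int, int, int]:
    """Output size and (before, after) padding for 'same' conv of size 3."""
    out = math.ceil(n / stride)
    pad = max((out - 1) * stride + KSIZE - n, 0)
    return out, pad // 2, pad - pad // 2


def _im2col(x: np.ndarray, stride: int):
    """(N,C,H,W) -> patches (N,Ho,Wo,C*9) plus geometry for the adjoint."""
    N, C, H, W = x.shape
    Ho, pt, pb = _same_geometry(H, stride)
    Wo, pl, pr = _same_geometry(W, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    cols = np.empty((N, Ho, Wo, C, KSIZE, KSIZE), dtype=x.dtype)
    for ki in range(KSIZE):
        for kj in range(KSIZE):
            cols[..., ki, kj] = xp[
                :, :, ki : ki + (Ho - 1) * stride + 1 : stride,
                kj : kj + (Wo - 1) * stride + 1 : stride,
            ].transpose(0, 2, 3, 1)
    geom = (N, C, H, W, Ho, Wo, pt, pl, xp.shape[2], xp.shape[3])
    return cols.reshape(N, Ho, Wo, C * KSIZE * KSIZE), geom


def _col2im(dcols: np.ndarray, geom, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back into an image)."""
    N, C, H, W, Ho, Wo, pt, pl, Hp, Wp = geom
    dcols = dcols.reshape(N, Ho, Wo, C, KSIZE, KSIZE)
    dxp = np.zeros((N, C, Hp, Wp), dtype=dcols.dtype)
    for ki in range(KSIZE):
        for kj in range(KSIZE):
            dxp[
                :, :, ki : ki + (Ho - 1) * stride + 1 : stride,
                kj : kj + (Wo - 1) * stride + 1 : stride,
            ] += dcols[..., ki, kj].transpose(0, 3, 1, 2)
    return dxp[:, :, pt : pt + H, pl : pl + W]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 2 by default, 'same' padding, He init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 2):
        self.stride = stride
        fan_in = c_in * KSIZE * KSIZE
        self.W = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), (c_out, c_in, KSIZE, KSIZE)
        ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, self._geom = _im2col(x, self.stride)
        N, Ho, Wo, ck = cols.shape
        self._cols = cols.reshape(-1, ck)
        out = self._cols @ self.W.reshape(self.W.shape[0], ck).T + self.b
        return out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, F, Ho, Wo = dy.shape
        dyr = dy.transpose(0, 2, 3, 1).reshape(-1, F)
        ck = self._cols.shape[1]
        self.grads[0][...] = (dyr.T @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = dyr.sum(axis=0)
        dcols = dyr @ self.W.reshape(F, ck)
        return _col2im(dcols.reshape(N, Ho, Wo, ck), self._geom, self.stride)


class ConvTranspose2D(Layer):
    """Adjoint of :class:`Conv2D`: upsamples by the stride, 'same' padding.

    The weight has conv orientation (c_in, c_out, 3, 3) where c_in is this
    layer's input channel count; forward is the conv backward-data pass.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 2):
        self.stride = stride
        fan_in = c_in * KSIZE * KSIZE
        self.W = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), (c_in, c_out, KSIZE, KSIZE)
        ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, y: np.ndarray) -> np.ndarray:
        N, F, Ho, Wo = y.shape
        c_out = self.W.shape[1]
        H, W = Ho * self.stride, Wo * self.stride
        # geometry of the conv this layer is the adjoint of
        Ho_c, pt, pb = _same_geometry(H, self.stride)
        Wo_c, pl, pr = _same_geometry(W, self.stride)
        assert (Ho_c, Wo_c) == (Ho, Wo)
        geom = (N, c_out, H, W, Ho, Wo, pt, pl, H + pt + pb, W + pl + pr)
        self._y = y
        ck = c_out * KSIZE * KSIZE
        dyr = y.transpose(0, 2, 3, 1).reshape(-1, F)
        cols = dyr @ self.W.reshape(F, ck)
        out = _col2im(cols.reshape(N, Ho, Wo, ck), geom, self.stride)
        return out + self.b[None, :, None, None]

    def backward(self, dz: np.ndarray) -> np.ndarray:
        N = dz.shape[0]
        cols, _ = _im2col(dz, self.stride)
        ck = cols.shape[-1]
        colsr = cols.reshape(-1, ck)
        F = self.W.shape[0]
        yr = self._y.transpose(0, 2, 3, 1).reshape(-1, F)
        self.grads[0][...] = (yr.T @ colsr).reshape(self.W.shape)
        self.grads[1][...] = dz.sum(axis=(0, 2, 3))
        dy = colsr @ self.W.reshape(F, ck).T
        Ho, Wo = self._y.shape[2], self._y.shape[3]
        return dy.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class RMSProp:
    """Keras-default RMSProp: lr 1e-3, rho 0.9, epsilon 1e-7."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.layers = [l for l in layers if l.params]
        self.cache = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        for layer, caches in zip(self.layers, self.cache):
            for p, g, c in zip(layer.params, layer.grads, caches):
                c *= self.rho
                c += (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(c) + self.eps)
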