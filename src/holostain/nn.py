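"""Minimal convolutional-network engine (numpy, CPU).

Implements exactly the pieces the virtual-staining GAN needs — 3×3
convolutions, leaky ReLU, stride-2 average pooling, bilinear 2×
upsampling, channel concatenation, fully connected layers, sigmoid — with
hand-written backward passes and an Adam optimizer.  Data layout is NCHW,
float32.  Every layer caches its last forward activations, so a backward
pass must follow the forward pass it corresponds to.

The engine is deliberately small: a fixed feed-forward graph per network,
no autodiff, no dynamic shapes beyond what the two architectures use.
Correctness is guarded by finite-difference gradient checks in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["truncated_normal", "Conv2d", "Linear", "LReLU", "Sigmoid",
           "AvgPool2", "BilinearUp2", "GlobalAvgPool", "Adam", "lrelu"]

F32 = np.float32


def lrelu(x: np.ndarray | float, slope: float = 0.1):
    """Leaky rectified linear unit: x for x > 0, slope·x otherwise."""
    return np.where(np.asarray(x) > 0, x, slope * np.asarray(x))


def truncated_normal(rng: np.random.Generator, shape, sigma: float = 0.05,
                     trunc: float = 2.0) -> np.ndarray:
    """Normal(0, sigma²) samples re-drawn until within ±trunc·sigma."""
    out = rng.normal(0.0, sigma, size=shape)
    bad = np.abs(out) > trunc * sigma
    while bad.any():
        out[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        bad = np.abs(out) > trunc * sigma
    return out.astype(F32)


class Layer:
    """Base class; layers with parameters override ``params``."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, 'same' zero padding, optional stride 2.

    Weights are truncated-normal (σ = 0.05, cut at 2σ); biases zero.
    Small fixed-σ weights start the network close to a shallow,
    bias-dominated map, which pairs well with Adam's bounded per-step
    movement on short training budgets.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, sigma: float = 0.05):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.W = truncated_normal(rng, (cin * k * k, cout), sigma)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, xp, ho, wo):
        k, s = self.k, self.stride
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            xp.shape[0], ho, wo, self.cin * k * k)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        assert c == self.cin, (c, self.cin)
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        if not train and h * w * self.cin > 2 ** 22:
            # low-memory inference: process output-row strips
            out = np.empty((n, self.cout, ho, wo), dtype=F32)
            strip = max(1, 2 ** 22 // max(1, wo * self.cin * k * k))
            for r0 in range(0, ho, strip):
                r1 = min(r0 + strip, ho)
                sub = xp[:, :, r0 * s:(r1 - 1) * s + k, :]
                win = sliding_window_view(sub, (k, k), axis=(2, 3))[:, :, ::s, ::s]
                cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                    n, r1 - r0, wo, self.cin * k * k)
                out[:, :, r0:r1, :] = (cols @ self.W + self.b).transpose(0, 3, 1, 2)
            return out
        cols = self._im2col(xp, ho, wo)
        y = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._xshape = (n, c, h, w)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, _, ho, wo = dy.shape
        k, s = self.k, self.stride
        p = k // 2
        dyc = dy.transpose(0, 2, 3, 1)  # (N, Ho, Wo, cout)
        cols2 = self._cols.reshape(-1, self.cin * k * k)
        dy2 = np.ascontiguousarray(dyc).reshape(-1, self.cout)
        self.dW += cols2.T @ dy2
        self.db += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(n, ho, wo, self.cin, k, k)
        _, c, h, w = self._xshape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + s * ho:s, v:v + s * wo:s] += \
                    dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 sigma: float = 0.05):
        self.W = truncated_normal(rng, (cin, cout), sigma)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class LReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class AvgPool2(Layer):
    """2×2 average pooling, stride 2."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * F32(0.25)


class BilinearUp2(Layer):
    """Bilinear 2× upsampling (half-pixel centers, clamped edges)."""

    _mats: dict[int, np.ndarray] = {}

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        if n not in cls._mats:
            A = np.zeros((2 * n, n), dtype=F32)
            for i in range(2 * n):
                x = (i + 0.5) / 2.0 - 0.5
                j0 = int(np.floor(x))
                t = x - j0
                j0c = min(max(j0, 0), n - 1)
                j1c = min(max(j0 + 1, 0), n - 1)
                A[i, j0c] += 1.0 - t
                A[i, j1c] += t
            cls._mats[n] = A
        return cls._mats[n]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        Ah, Aw = self._matrix(h), self._matrix(w)
        self._shape = (h, w)
        return np.einsum("ih,nchw,jw->ncij", Ah, x, Aw, optimize=True)

    def backward(self, dy):
        h, w = self._shape
        Ah, Aw = self._matrix(h), self._matrix(w)
        return np.einsum("ih,ncij,jw->nchw", Ah, dy, Aw, optimize=True)


class GlobalAvgPool(Layer):
    """Per-channel spatial average -> (N, C).

    On a 256² input to the discriminator the final map is 8×8, so this is
    exactly the 8×8 average-pooling that flattens to a 2048-vector.
    """

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._shape).astype(F32)


class Adam:
    """Adaptive-moment optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
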