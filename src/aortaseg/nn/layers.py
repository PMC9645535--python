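"""NumPy layers with explicit forward/backward passes.

Tensors are single samples laid out ``(channels, X, Y, Z)`` in float32.
Convolutions are evaluated as one BLAS matrix product per kernel offset on
shifted views of the padded input, which keeps Python overhead negligible
for the 3^3 kernels used here.  Each layer caches what its backward pass
needs; parameter gradients accumulate into ``.grads`` until the optimizer
consumes them.
"""

from __future__ import annotations

import itertools

import numpy as np

F32 = np.float32


class Layer:
    """Base: stateless unless it owns parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding, He-initialised."""

    def __init__(self, cin: int, cout: int, ksize: int = 3,
                 rng: np.random.Generator | None = None):
        if ksize % 2 != 1:
            raise ValueError("only odd kernel sizes supported")
        rng = rng or np.random.default_rng(0)
        fan_in = cin * ksize**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(ksize**3, cout, cin)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = ksize
        self.cin, self.cout = cin, cout
        self.offsets = list(itertools.product(range(ksize), repeat=3))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        self._shape = (d, h, w_)
        n = d * h * w_
        out = np.empty((self.cout, n), dtype=F32)
        out[:] = self.b[:, None]
        for o, (dz, dy, dx) in enumerate(self.offsets):
            patch = xp[:, dz:dz + d, dy:dy + h, dx:dx + w_].reshape(self.cin, n)
            out += self.w[o] @ patch
        return out.reshape(self.cout, d, h, w_)

    def backward(self, g: np.ndarray) -> np.ndarray:
        d, h, w_ = self._shape
        n = d * h * w_
        gf = g.reshape(self.cout, n)
        self.gb += gf.sum(axis=1)
        p = self.k // 2
        gxp = np.zeros_like(self._xp)
        for o, (dz, dy, dx) in enumerate(self.offsets):
            patch = self._xp[:, dz:dz + d, dy:dy + h, dx:dx + w_].reshape(self.cin, n)
            self.gw[o] += gf @ patch.T
            gxp[:, dz:dz + d, dy:dy + h, dx:dx + w_] += \
                (self.w[o].T @ gf).reshape(self.cin, d, h, w_)
        self._xp = None
        return gxp[:, p:p + d, p:p + h, p:p + w_] if p else gxp


class InstanceNorm(Layer):
    """Per-channel normalisation over the spatial axes with affine params."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        xf = x.reshape(c, -1)
        mu = xf.mean(axis=1, keepdims=True)
        var = xf.var(axis=1, keepdims=True)
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = ((xf - mu) * self._inv).astype(F32)
        out = self.gamma[:, None] * self._xhat + self.beta[:, None]
        return out.reshape(x.shape).astype(F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c = g.shape[0]
        gf = g.reshape(c, -1)
        n = gf.shape[1]
        self.gbeta += gf.sum(axis=1)
        self.ggamma += (gf * self._xhat).sum(axis=1)
        gxhat = gf * self.gamma[:, None]
        gx = (self._inv / n) * (
            n * gxhat
            - gxhat.sum(axis=1, keepdims=True)
            - self._xhat * (gxhat * self._xhat).sum(axis=1, keepdims=True)
        )
        return gx.reshape(g.shape).astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._m = x > 0
        return np.where(self._m, x, 0).astype(F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._m, g, 0).astype(F32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = (1.0 / (1.0 + np.exp(-np.clip(x, -80.0, 80.0)))).astype(F32)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return (g * self._y * (1.0 - self._y)).astype(F32)


class Softmax(Layer):
    """Softmax over the channel axis (per-voxel probability simplex)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=0, keepdims=True)
        e = np.exp(z)
        self._p = (e / e.sum(axis=0, keepdims=True)).astype(F32)
        return self._p

    def backward(self, g: np.ndarray) -> np.ndarray:
        dot = (g * self._p).sum(axis=0, keepdims=True)
        return (self._p * (g - dot)).astype(F32)


def _blocks(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (C, D/2, H/2, W/2, 8) view-by-copy of 2x2x2 blocks."""
    c, d, h, w = x.shape
    return (x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8))


def _unblocks(b: np.ndarray, shape) -> np.ndarray:
    c, d, h, w = shape
    return (b.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w))


class MaxPool2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:]):
            raise ValueError(f"MaxPool2 needs even spatial dims, got {x.shape}")
        b = _blocks(x)
        self._idx = b.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(b, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b = np.zeros(g.shape + (8,), dtype=F32)
        np.put_along_axis(b, self._idx[..., None], g[..., None], axis=-1)
        return _unblocks(b, self._shape)


class AvgPool2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:]):
            raise ValueError(f"AvgPool2 needs even spatial dims, got {x.shape}")
        self._shape = x.shape
        return _blocks(x).mean(axis=-1).astype(F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b = np.repeat((g / 8.0)[..., None], 8, axis=-1).astype(F32)
        return _unblocks(b, self._shape)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling; backward is the matching sum-pool."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, 1), 2, 2), 2, 3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return _blocks(g).sum(axis=-1).astype(F32)


class Adam:
    """Adaptive-moment optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = [(p, g) for lay in layers for p, g in zip(lay.params(), lay.grads())]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
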