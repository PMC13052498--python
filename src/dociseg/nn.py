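"""Minimal CNN building blocks on numpy with analytic backpropagation.

Implements exactly the layers the segmentation network needs — 2-D
convolution (im2col), batch normalization, ReLU/sigmoid, spatial and plain
dropout, squeeze-and-excitation, 2× nearest-neighbor upsampling, channel
concatenation — plus the Adam optimizer.  Tensors are NHWC float64; gradients
are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(extent: int, k: int, s: int) -> tuple[int, int, int]:
    """TF-style 'same' padding: output ceil(extent/s); pad split low/high."""
    out = -(-extent // s)
    total = max((out - 1) * s + k - extent, 0)
    lo = total // 2
    return out, lo, total - lo


class Conv2D(Layer):
    """k×k convolution, stride s, 'same' padding, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = Param(rng.standard_normal((k * k * cin, cout)) * scale)
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (N, OH, OW, C, k, k) -> cols ordered (k, k, C)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * oh * ow, k * k * c
        )
        self._cache = (cols, xp.shape, (pt, pb, pl, pr), (n, oh, ow))
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, oh, ow, self.cout)

    def backward(self, g):
        cols, xpshape, (pt, pb, pl, pr), (n, oh, ow) = self._cache
        k, s, c = self.k, self.stride, self.cin
        gf = g.reshape(n * oh * ow, self.cout)
        self.W.grad += cols.T @ gf
        self.b.grad += gf.sum(axis=0)
        gcols = (gf @ self.W.value.T).reshape(n, oh, ow, k, k, c)
        gxp = np.zeros(xpshape)
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += (
                    gcols[:, :, :, i, j, :]
                )
        hp, wp = xpshape[1], xpshape[2]
        return gxp[:, pt : hp - pb, pl : wp - pr, :]


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, training, x.shape)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g):
        xhat, invstd, training, shape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += g.sum(axis=(0, 1, 2))
        gxhat = g * self.gamma.value
        if not training:
            return gxhat * invstd
        m = shape[0] * shape[1] * shape[2]
        return (invstd / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 1, 2))
            - xhat * (gxhat * xhat).sum(axis=(0, 1, 2))
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


class SpatialDropout(Layer):
    """Drops whole feature channels (per sample) during training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = self.rng.random((x.shape[0], 1, 1, x.shape[3])) >= self.rate
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dropout(SpatialDropout):
    """Elementwise dropout."""

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation: global-average squeeze, gated bottleneck
    excitation, channel-wise rescale."""

    def __init__(self, c: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(c // reduction, 1)
        self.W1 = Param(rng.standard_normal((c, hidden)) * np.sqrt(2.0 / c))
        self.b1 = Param(np.zeros(hidden))
        self.W2 = Param(rng.standard_normal((hidden, c)) * np.sqrt(1.0 / hidden))
        self.b2 = Param(np.zeros(c))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, training=False):
        z = x.mean(axis=(1, 2))
        hpre = z @ self.W1.value + self.b1.value
        h = np.maximum(hpre, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.W2.value + self.b2.value)))
        self._cache = (x, z, hpre, h, s)
        return x * s[:, None, None, :]

    def backward(self, g):
        x, z, hpre, h, s = self._cache
        hw = x.shape[1] * x.shape[2]
        gx = g * s[:, None, None, :]
        gs = (g * x).sum(axis=(1, 2))
        dpre2 = gs * s * (1.0 - s)
        self.W2.grad += h.T @ dpre2
        self.b2.grad += dpre2.sum(axis=0)
        gh = (dpre2 @ self.W2.value.T) * (hpre > 0)
        self.W1.grad += z.T @ gh
        self.b1.grad += gh.sum(axis=0)
        gz = gh @ self.W1.value.T
        return gx + gz[:, None, None, :] / hw


class Upsample2x(Layer):
    """2× nearest-neighbor upsampling."""

    def forward(self, x, training=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g):
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Concat(Layer):
    """Concatenate two NHWC tensors along channels (skip first)."""

    def forward_pair(self, skip: np.ndarray, x: np.ndarray) -> np.ndarray:
        self._split = skip.shape[3]
        return np.concatenate([skip, x], axis=3)

    def backward(self, g):
        return g[..., : self._split], g[..., self._split :]


def run_forward(layers: list[Layer], x: np.ndarray, training: bool) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, training)
    return x


def run_backward(layers: list[Layer], g: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        g = layer.backward(g)
    return g


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
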