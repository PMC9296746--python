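"""Minimal NumPy neural-network layers with manual backpropagation.

Tensors are float32 and channel-last, shape (N, D, H, W, C), which keeps
every convolution a GEMM over the trailing axis.  Each layer caches what
its backward pass needs during ``forward``; ``backward`` consumes the
cache, accumulates parameter gradients and returns the input gradient.
The set of layers is exactly what the u-net needs: 3x3x3 "same"
convolutions, instance normalization, (leaky) ReLU, 2x max-pooling,
2x2x2 stride-2 transposed convolutions and 1x1x1 convolutions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv3x3", "InstanceNorm", "LeakyReLU", "ReLU",
    "MaxPool2", "UpConv2", "Conv1x1", "l1_loss",
]

F32 = np.float32


class Param:
    """A learnable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    params: tuple[Param, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3D convolution, kernel 3, stride 1, zero 'same' padding.

    Weights (3, 3, 3, Cin, Cout), He-normal initialized.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 27))
        self.w = Param(rng.normal(0.0, std, size=(3, 3, 3, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.params = (self.w, self.b)
        self._xp = None

    def forward(self, x):
        n, d, h, w_, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        out = None
        wv = self.w.value
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    term = xp[:, i:i + d, j:j + h, k:k + w_, :] @ wv[i, j, k]
                    out = term if out is None else out + term
        out += self.b.value
        return out

    def backward(self, gy):
        xp = self._xp
        n, d, h, w_, _ = gy.shape
        gxp = np.zeros_like(xp)
        wv = self.w.value
        gw = self.w.grad
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[:, i:i + d, j:j + h, k:k + w_, :]
                    gw[i, j, k] += np.tensordot(
                        xs, gy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                    gxp[:, i:i + d, j:j + h, k:k + w_, :] += gy @ wv[i, j, k].T
        self.b.grad += gy.sum(axis=(0, 1, 2, 3))
        self._xp = None
        return gxp[:, 1:-1, 1:-1, 1:-1, :]


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes,
    without learned affine parameters."""

    def __init__(self, eps: float = 1e-5):
        self.eps = F32(eps)
        self._cache = None

    def forward(self, x):
        mu = x.mean(axis=(1, 2, 3), keepdims=True, dtype=F32)
        var = x.var(axis=(1, 2, 3), keepdims=True, dtype=F32)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(F32))
        return xhat

    def backward(self, gy):
        xhat, inv = self._cache
        self._cache = None
        m1 = gy.mean(axis=(1, 2, 3), keepdims=True, dtype=F32)
        m2 = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True, dtype=F32)
        return inv * (gy - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = F32(negative_slope)
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        mask = self._mask
        self._mask = None
        return np.where(mask, gy, self.slope * gy)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, gy):
        mask = self._mask
        self._mask = None
        return np.where(mask, gy, F32(0))


class MaxPool2(Layer):
    """2x2x2 max pooling with stride 2."""

    def __init__(self):
        self._cache = None

    def forward(self, x):
        n, d, h, w, c = x.shape
        r = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            n, d // 2, h // 2, w // 2, c, 8)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, gy):
        idx, shape = self._cache
        self._cache = None
        n, d, h, w, c = shape
        g = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=F32)
        np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
        g = g.transpose(0, 1, 5, 2, 6, 3, 7, 4)
        return g.reshape(shape)


class UpConv2(Layer):
    """Transposed convolution, kernel 2x2x2, stride 2 (doubles each
    spatial dimension)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cin, 8 * cout)))
        self.b = Param(np.zeros(cout))
        self.cout = cout
        self.params = (self.w, self.b)
        self._x = None

    def forward(self, x):
        n, d, h, w_, c = x.shape
        self._x = x
        t = x @ self.w.value  # (n, d, h, w, 8*cout)
        t = t.reshape(n, d, h, w_, 2, 2, 2, self.cout)
        t = t.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return t.reshape(n, 2 * d, 2 * h, 2 * w_, self.cout) + self.b.value

    def backward(self, gy):
        x = self._x
        self._x = None
        n, d2, h2, w2, co = gy.shape
        d, h, w_ = d2 // 2, h2 // 2, w2 // 2
        self.b.grad += gy.sum(axis=(0, 1, 2, 3))
        g = gy.reshape(n, d, 2, h, 2, w_, 2, co)
        g = g.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(n, d, h, w_, 8 * co)
        self.w.grad += np.tensordot(x, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        return g @ self.w.value.T


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cin, cout)))
        self.b = Param(np.full(cout, bias_init))
        self.params = (self.w, self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        x = self._x
        self._x = None
        self.w.grad += np.tensordot(x, gy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.b.grad += gy.sum(axis=(0, 1, 2, 3))
        return gy @ self.w.value.T


def l1_loss(pred: np.ndarray, target: np.ndarray
            ) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff, dtype=F32).mean())
    grad = np.sign(diff, dtype=F32) / F32(diff.size)
    return loss, grad
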