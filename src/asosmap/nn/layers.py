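"""Minimal neural-network layers with explicit forward/backward passes.

All layers operate on NCHW float arrays and keep whatever dtype they are
built with (float32 for training speed, float64 in numerical tests).
Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad`` during ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "MaxPool2d",
    "BilinearUpsample2x",
    "Linear",
    "Flatten",
    "Sequential",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C*k*k) patch matrix (materialized copy)."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,Ho*,Wo*,k,k
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col matmul.

    Backward recomputes the patch matrix from the cached input instead of
    caching it, trading a little compute for a large memory saving in the
    decoder layers.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init, leaky-ReLU friendly
        self.w = Param((rng.standard_normal((c_out, c_in, k, k)) * scale).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.k, self.stride, self.pad = k, stride, pad
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def _padded(self, x: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return x
        p = self.pad
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        k, s = self.k, self.stride
        cols = _im2col(self._padded(x), k, s)
        c_out = self.w.data.shape[0]
        wmat = self.w.data.reshape(c_out, -1)
        y = cols @ wmat.T + self.b.data
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        k, s, p = self.k, self.stride, self.pad
        n, c_out, ho, wo = gy.shape
        xp = self._padded(x)

        # weight/bias grads: correlate input patches with output grads
        cols = _im2col(xp, k, s)  # N,Ho,Wo,Cin*k*k
        gflat = gy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        gw = gflat.T @ cols.reshape(-1, cols.shape[-1])
        self.w.grad += gw.reshape(self.w.data.shape)
        self.b.grad += gy.sum(axis=(0, 2, 3))

        # input grad: full correlation of the (dilated) output grad with the
        # spatially flipped kernel, channels swapped
        if s > 1:
            gyd = np.zeros((n, c_out, (ho - 1) * s + 1, (wo - 1) * s + 1), dtype=gy.dtype)
            gyd[:, :, ::s, ::s] = gy
        else:
            gyd = gy
        gyp = np.pad(gyd, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        wflip = self.w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # Cin,Cout,k,k
        cols_g = _im2col(gyp, k, 1)
        gx_full = cols_g @ wflip.reshape(wflip.shape[0], -1).T
        gx_full = gx_full.transpose(0, 3, 1, 2)
        # crop padding; pad right/bottom with zeros for strided leftover pixels
        hp, wp = xp.shape[2], xp.shape[3]
        gxp = np.zeros_like(xp)
        gxp[:, :, : gx_full.shape[2], : gx_full.shape[3]] = gx_full[:, :, :hp, :wp]
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._cache = (xhat, invstd, train)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.data[:, None, None]
        if not train:
            return gy * g * invstd[:, None, None]
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        gxhat = gy * g
        return (invstd[:, None, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.slope * gy)


class Tanh(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * (1.0 - self._y * self._y)


class Sigmoid(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1.0 - self._y)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2. Ties route the gradient to the first max."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gr, self._idx[..., None], gy[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gr.reshape(n, c, h, w)


def _interp_matrix(h_out: int, h_in: int, dtype) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (edge-clamped)."""
    a = np.zeros((h_out, h_in), dtype=dtype)
    scale = h_in / h_out
    for i in range(h_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), h_in - 1)
        hi_c = min(max(lo + 1, 0), h_in - 1)
        a[i, lo_c] += 1.0 - t
        a[i, hi_c] += t
    return a


class BilinearUpsample2x(Module):
    """Doubles spatial size with bilinear interpolation (no checkerboard)."""

    _cache_mats: dict = {}

    def _mat(self, h_in: int, dtype) -> np.ndarray:
        key = (h_in, np.dtype(dtype).str)
        if key not in self._cache_mats:
            self._cache_mats[key] = _interp_matrix(2 * h_in, h_in, dtype)
        return self._cache_mats[key]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ah, aw = self._mat(h, x.dtype), self._mat(w, x.dtype)
        self._mats = (ah, aw)
        y = np.tensordot(x, aw, axes=([3], [1]))          # N,C,H,2W
        y = np.tensordot(y, ah, axes=([2], [1]))          # N,C,2W,2H
        return np.ascontiguousarray(y.transpose(0, 1, 3, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        ah, aw = self._mats
        g = np.tensordot(gy, aw, axes=([3], [0]))         # N,C,2H,W
        g = np.tensordot(g, ah, axes=([2], [0]))          # N,C,W,H
        return np.ascontiguousarray(g.transpose(0, 1, 3, 2))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = Param((rng.standard_normal((n_out, n_in)) * scale).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.data


class Flatten(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy
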