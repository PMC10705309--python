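"""Layers with explicit forward/backward passes (float32, NCHW/NCDHW)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Parameter", "Layer", "Conv", "BatchNorm", "ReLU", "MaxPool2x", "ConvTranspose2x"]

# einsum scripts per spatial ndim: forward, weight-grad, input-grad
_CONV_FWD = {2: "bchwij,ocij->bohw", 3: "bcdhwijk,ocijk->bodhw"}
_CONV_DW = {2: "bchwij,bohw->ocij", 3: "bcdhwijk,bodhw->ocijk"}
_CONV_DX = {2: "bohwij,ocij->bchw", 3: "bodhwijk,ocijk->bcdhw"}


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv(Layer):
    """N-D convolution, odd kernel, stride 1, "same" zero padding."""

    def __init__(self, ndim: int, in_channels: int, out_channels: int,
                 kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.ndim = ndim
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size ** ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels) + (kernel_size,) * ndim)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))

    def parameters(self):
        return [self.weight, self.bias]

    def _windows(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            pad = [(0, 0), (0, 0)] + [(self.pad, self.pad)] * self.ndim
            x = np.pad(x, pad)
        return sliding_window_view(x, (self.k,) * self.ndim,
                                   axis=tuple(range(2, 2 + self.ndim)))

    def forward(self, x, train):
        win = self._windows(x)
        if train:
            self._win = win
        out = np.einsum(_CONV_FWD[self.ndim], win, self.weight.value, optimize=True)
        out += self.bias.value.reshape((1, -1) + (1,) * self.ndim)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, g):
        self.weight.grad += np.einsum(_CONV_DW[self.ndim], self._win, g, optimize=True)
        self.bias.grad += g.sum(axis=(0,) + tuple(range(2, 2 + self.ndim)))
        del self._win
        w_flip = self.weight.value[(slice(None), slice(None)) + (slice(None, None, -1),) * self.ndim]
        gwin = self._windows(g)
        dx = np.einsum(_CONV_DX[self.ndim], gwin, w_flip, optimize=True)
        return np.ascontiguousarray(dx, dtype=np.float32)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(self._shape(x))) * inv.reshape(self._shape(x))
        if train:
            self._xhat, self._inv, self._axes = xhat, inv, axes
        return (self.gamma.value.reshape(self._shape(x)) * xhat
                + self.beta.value.reshape(self._shape(x))).astype(np.float32)

    def backward(self, g):
        xhat, inv, axes = self._xhat, self._inv, self._axes
        del self._xhat
        n = g.size // g.shape[1]
        dbeta = g.sum(axis=axes)
        dgamma = (g * xhat).sum(axis=axes)
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        shape = self._shape(g)
        coef = (self.gamma.value * inv / n).reshape(shape)
        dx = coef * (n * g - dbeta.reshape(shape) - xhat * dgamma.reshape(shape))
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g):
        dx = g * self._mask
        del self._mask
        return dx


class MaxPool2x(Layer):
    """Max pooling with window and stride 2 along every spatial axis."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def forward(self, x, train):
        b, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial dims {spatial} not divisible by 2 for max-pool")
        halves = tuple(s // 2 for s in spatial)
        shape = (b, c) + sum(((h, 2) for h in halves), ())
        xr = x.reshape(shape)
        # move the window axes (3,5[,7]) to the back
        win_axes = tuple(3 + 2 * i for i in range(self.ndim))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(self.ndim))
        xr = xr.transpose(keep_axes + win_axes).reshape((b, c) + halves + (2 ** self.ndim,))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_spatial = idx, spatial
        return np.ascontiguousarray(out)

    def backward(self, g):
        idx, spatial = self._idx, self._in_spatial
        del self._idx
        b, c = g.shape[:2]
        halves = tuple(s // 2 for s in spatial)
        flat = np.zeros((b, c) + halves + (2 ** self.ndim,), dtype=g.dtype)
        np.put_along_axis(flat, idx[..., None], g[..., None], axis=-1)
        flat = flat.reshape((b, c) + halves + (2,) * self.ndim)
        # undo the transpose: interleave half axes with window axes
        order = (0, 1)
        for i in range(self.ndim):
            order += (2 + i, 2 + self.ndim + i)
        return np.ascontiguousarray(flat.transpose(order).reshape((b, c) + spatial))


class ConvTranspose2x(Layer):
    """Transposed convolution with kernel 2 and stride 2 (no overlap)."""

    def __init__(self, ndim: int, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        self.ndim = ndim
        fan_in = in_channels * 2 ** ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(in_channels, out_channels) + (2,) * ndim)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))
        self._fwd = {2: "bchw,coij->bohwij", 3: "bcdhw,coijk->bodhwijk"}[ndim]
        self._dx = {2: "bohwij,coij->bchw", 3: "bodhwijk,coijk->bcdhw"}[ndim]
        self._dw = {2: "bchw,bohwij->coij", 3: "bcdhw,bodhwijk->coijk"}[ndim]

    def parameters(self):
        return [self.weight, self.bias]

    def _interleave(self, x):
        # (B,O,*S,*2) -> (B,O,*2S)
        b, o = x.shape[:2]
        spatial = x.shape[2:2 + self.ndim]
        order = (0, 1)
        for i in range(self.ndim):
            order += (2 + i, 2 + self.ndim + i)
        out_shape = (b, o) + tuple(2 * s for s in spatial)
        return x.transpose(order).reshape(out_shape)

    def _deinterleave(self, g):
        b, o = g.shape[:2]
        halves = tuple(s // 2 for s in g.shape[2:])
        shape = (b, o) + sum(((h, 2) for h in halves), ())
        keep = (0, 1) + tuple(2 + 2 * i for i in range(self.ndim))
        win = tuple(3 + 2 * i for i in range(self.ndim))
        return g.reshape(shape).transpose(keep + win)

    def forward(self, x, train):
        if train:
            self._x = x
        out = np.einsum(self._fwd, x, self.weight.value, optimize=True)
        out = self._interleave(out)
        out += self.bias.value.reshape((1, -1) + (1,) * self.ndim)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, g):
        gr = self._deinterleave(g)
        self.bias.grad += g.sum(axis=(0,) + tuple(range(2, 2 + self.ndim)))
        self.weight.grad += np.einsum(self._dw, self._x, gr, optimize=True)
        del self._x
        dx = np.einsum(self._dx, gr, self.weight.value, optimize=True)
        return np.ascontiguousarray(dx, dtype=np.float32)
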