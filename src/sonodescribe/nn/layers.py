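"""Forward/backward layer primitives (NCHW, float32 by default)."""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """Unfold (N, C, H, W) into (N*OH*OW, C*k*k) patch rows."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    col = np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * oh * ow, c * k * k)
    return col, (n, c, h, w, oh, ow)


def col2im(dcol: np.ndarray, meta: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Fold patch-row gradients back onto the padded input, then crop."""
    n, c, h, w, oh, ow = meta
    dview = dcol.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dview[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    """Base: parameters and their gradients live in parallel dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 'same' convolution with He-initialized weights."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.k, self.pad, self.stride = k, k // 2, 1
        self.params["W"] = (rng.standard_normal((out_ch, fan_in))
                            * math.sqrt(2.0 / fan_in)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        col, meta = im2col(x, self.k, self.stride, self.pad)
        out = col @ self.params["W"].T + self.params["b"]
        n, _, _, _, oh, ow = meta
        self._cache = (col, meta) if train else None
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, meta = self._cache
        n, _, _, _, oh, ow = meta
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, -1)
        self.grads["W"] = dflat.T @ col
        self.grads["b"] = dflat.sum(axis=0)
        dcol = dflat @ self.params["W"]
        return col2im(dcol, meta, self.k, self.stride, self.pad)


class MaxPool2d(Layer):
    """2x2/stride-2 max pooling with floor semantics for odd sides."""

    def __init__(self) -> None:
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        xc = x[:, :, :oh * 2, :ow * 2]
        win = xc.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, oh, ow, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w, oh, ow)) if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w, oh, ow) = self._cache
        dwin = np.zeros((n, c, oh, ow, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, :oh * 2, :ow * 2] = dwin.reshape(
            n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, oh * 2, ow * 2)
        return dx


class GELU(Layer):
    """Exact GELU: x * Phi(x)."""

    def __init__(self) -> None:
        super().__init__()
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return (0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return (dout * (cdf + x * pdf)).astype(dout.dtype)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = (rng.standard_normal((out_dim, in_dim))
                            * math.sqrt(2.0 / in_dim)).astype(dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class BatchNormRows(Layer):
    """Batch normalization of the feature space F (N, g*g, d).

    Each of the d feature dimensions is normalized over all spatial cells of
    all images in the batch, with learnable scale/shift and running statistics
    for inference.  An epsilon guard keeps constant inputs finite.
    """

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(d, dtype=dtype)
        self.params["beta"] = np.zeros(d, dtype=dtype)
        self.running_mean = np.zeros(d, dtype=dtype)
        self.running_var = np.ones(d, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, g2, d = x.shape
        flat = x.reshape(n * g2, d)
        if train:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean) * inv
        out = xhat * self.params["gamma"] + self.params["beta"]
        self._cache = (xhat, inv, (n, g2, d)) if train else None
        return out.reshape(n, g2, d).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, (n, g2, d) = self._cache
        dflat = dout.reshape(n * g2, d)
        m = n * g2
        self.grads["gamma"] = (dflat * xhat).sum(axis=0)
        self.grads["beta"] = dflat.sum(axis=0)
        dxhat = dflat * self.params["gamma"]
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=0)
                          - xhat * (dxhat * xhat).sum(axis=0))
        return dx.reshape(n, g2, d).astype(dout.dtype)
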