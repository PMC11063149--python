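"""Minimal CNN building blocks on numpy arrays with explicit backward passes.

Each layer caches what its backward pass needs during ``forward`` and returns
the gradient with respect to its input from ``backward``; learnable arrays are
wrapped in :class:`Param` so an optimizer can walk them generically.  The
backward implementations are validated against central finite differences in
the test suite.

Convolution uses an im2col formulation: patches are gathered with
``sliding_window_view`` and the convolution becomes one matrix product, which
keeps both passes inside BLAS.  ``float32`` is the working precision.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "GlobalAvgPool",
    "softmax_cross_entropy",
]


class Param:
    """A learnable array and its gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Conv2d:
    """2-D convolution, square kernel, symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.w = Param(
            (rng.standard_normal((out_channels, in_channels, kernel, kernel)) * scale
             ).astype(dtype)
        )
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wmat = self.w.data.reshape(self.w.data.shape[0], -1)
        out = cols @ wmat.T + self.b.data
        self._cache = (cols, (n, c, h, w), (ho, wo))
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        cout = dout.shape[1]
        dout_r = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.w.grad = (dout_r.T @ cols).reshape(self.w.data.shape)
        self.b.grad = dout_r.sum(axis=0)
        dcols = (dout_r @ self.w.data.reshape(cout, -1)).reshape(
            n, ho, wo, c, k, k
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics; eval mode (used for
    inference and attribution) applies the frozen running statistics, making
    the layer an affine map whose backward pass is a per-channel scaling.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.gamma.data[None, :, None, None]
        b = self.beta.data[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(x.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(x.dtype)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
            self._cache = ("train", xhat, inv_std)
            return g * xhat + b
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv_std[
            None, :, None, None
        ]
        self._cache = ("eval", xhat, inv_std)
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mode, xhat, inv_std = self._cache
        self.gamma.grad = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if mode == "eval":
            return dout * g * inv_std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        return (
            inv_std[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool2d:
    """Non-overlapping k x k average pooling (input sides divisible-truncated).

    Used for downsampling instead of strided convolution where gradient
    aliasing matters: the backward pass spreads gradient uniformly over each
    window rather than concentrating it on the stride-sampled pixels.
    """

    def __init__(self, k: int = 2):
        self.k = k
        self._shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        self._shape = x.shape
        trimmed = x[:, :, : ho * k, : wo * k]
        return trimmed.reshape(n, c, ho, k, wo, k).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k = self.k
        ho, wo = h // k, w // k
        dx = np.zeros(self._shape, dtype=dout.dtype)
        spread = np.broadcast_to(
            dout[:, :, :, None, :, None] / (k * k), (n, c, ho, k, wo, k)
        )
        dx[:, :, : ho * k, : wo * k] = spread.reshape(n, c, ho * k, wo * k)
        return dx


class GlobalAvgPool:
    """Adaptive average pooling to 1x1: makes the head input-size agnostic."""

    def __init__(self):
        self._shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(dout.dtype)


class Linear:
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.w = Param(
            (rng.standard_normal((out_features, in_features)) * scale).astype(dtype)
        )
        self.b = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad = dout.T @ self._x
        self.b.grad = dout.sum(axis=0)
        return dout @ self.w.data


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
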