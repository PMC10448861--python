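"""Minimal numpy building blocks for 1D convolutional networks.

Self-contained layers (dilated same-padded 1D convolution, batch
normalization, ReLU, global average pooling, dense) with hand-written
backpropagation and an Adam optimizer. Inputs are channels-first
``(N, C, L)`` arrays. Each layer caches what its backward pass needs on
forward; ``backward`` must therefore follow the matching ``forward``.

Convolutions are evaluated as im2col matrix products; the gradient with
respect to the input of a stride-1, same-padded, odd-width convolution is
itself such a convolution with the kernel flipped and its channel axes
swapped, which keeps the backward pass on the same BLAS path.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


def _im2col(x: np.ndarray, width: int, dilation: int) -> np.ndarray:
    """(N, C, L) -> (N*L, C*width) patches for a same-padded dilated conv."""
    n, c, length = x.shape
    pad = (width - 1) // 2 * dilation
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    idx = np.arange(length)[:, None] + np.arange(width)[None, :] * dilation
    cols = xp[:, :, idx]                       # (N, C, L, W)
    return cols.transpose(0, 2, 1, 3).reshape(n * length, c * width)


class Layer:
    """Base class: parameters and their gradients live in parallel dicts."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def astype(self, dtype) -> None:
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)


class Conv1D(Layer):
    """Stride-1, same-padded 1D convolution with dilation.

    Weights use He (variance-scaling) initialization; ``width`` must be odd
    so that output length equals input length.
    """

    def __init__(self, in_ch: int, out_ch: int, width: int, dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        if width % 2 == 0:
            raise ValueError("kernel width must be odd for same padding")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.width, self.dilation = width, dilation
        std = np.sqrt(2.0 / (in_ch * width))
        self.params["W"] = rng.normal(0.0, std, (in_ch * width, out_ch)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._cols: Optional[np.ndarray] = None
        self._shape: Tuple[int, int, int] = (0, 0, 0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        cols = _im2col(x, self.width, self.dilation)
        y = cols @ self.params["W"] + self.params["b"]
        if training:
            self._cols, self._shape = cols, (n, c, length)
        return y.reshape(n, length, self.out_ch).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dyf = dy.transpose(0, 2, 1).reshape(n * length, self.out_ch)
        self.grads["W"] = self._cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        self._cols = None
        # dx = conv(dy) with the flipped kernel, channel axes swapped
        w = self.params["W"].reshape(self.in_ch, self.width, self.out_ch)
        wt = w[:, ::-1, :].transpose(2, 1, 0).reshape(
            self.out_ch * self.width, self.in_ch
        )
        cols = _im2col(dy, self.width, self.dilation)
        dx = cols @ wt
        return dx.reshape(n, length, self.in_ch).transpose(0, 2, 1)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the batch and position axes."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv[None, :, None]
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(x.dtype)
        mean = self.running_mean.astype(x.dtype)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        return g * (x - mean[None, :, None]) * inv[None, :, None] + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return (inv[None, :, None] * term).astype(dy.dtype)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C) mean over positions."""

    def __init__(self) -> None:
        super().__init__()
        self._length = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, std, (in_features, out_features)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(out_features, dtype=np.float32)
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params["W"].T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy on logits.

    Returns the weighted mean loss and its gradient with respect to the
    logits. Uses the softplus form for numerical stability.
    """
    z = logits.astype(np.float64)
    y = labels.astype(np.float64)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(weights * (softplus - y * z)))
    dz = weights * (sigmoid(z) - y) / len(z)
    return loss, dz


class Adam:
    """Adam optimizer over a list of layers' parameter dicts."""

    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v, dtype=np.float64) for k, v in l.params.items()}
            for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v, dtype=np.float64) for k, v in l.params.items()}
            for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for key, param in layer.params.items():
                grad = layer.grads[key].astype(np.float64)
                m[key] = b1 * m[key] + (1 - b1) * grad
                v[key] = b2 * v[key] + (1 - b2) * grad * grad
                update = (m[key] / corr1) / (np.sqrt(v[key] / corr2) + self.eps)
                layer.params[key] = (param - self.lr * update).astype(param.dtype)
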