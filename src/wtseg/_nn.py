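"""Minimal CPU conv-net engine: layers with explicit forward/backward.

Data layout is NHWC float32 throughout.  Convolutions are stride-1,
odd-kernel, zero-padded 'same', computed by im2col + GEMM; the input
gradient is the full correlation of the output gradient with the
spatially flipped, channel-transposed kernel, so no scatter-add is
needed.  Only what the two segmentation families require is provided:
3x3/1x1 conv, ReLU, 2x2 max/average pooling, nearest-neighbor 2x
upsampling and channel concatenation, plus Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "AvgPool2",
    "UpsampleNearest2",
    "concat_channels",
    "split_channels",
    "Adam",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix with 'same' zero padding."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * c
    )


class Conv2d:
    """Stride-1 'same' convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        scale = np.sqrt(2.0 / (k * k * c_in))  # He initialization
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        if self.k == 1:
            cols = x.reshape(-1, self.c_in)
        else:
            cols = _im2col(x, self.k)
        self._cols = cols
        y = cols @ self.W.reshape(-1, self.c_out) + self.b
        n, h, w, _ = x.shape
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        dyf = dy.reshape(-1, self.c_out)
        self.dW += (self._cols.T @ dyf).reshape(self.W.shape)
        self.db += dyf.sum(axis=0)
        if self.k == 1:
            dx = dyf @ self.W.reshape(self.c_in, self.c_out).T
            return dx.reshape(self._shape)
        w_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # k,k,c_out,c_in
        cols = _im2col(dy, self.k)
        dx = cols @ w_flip.reshape(-1, self.c_in)
        return dx.reshape(self._shape)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


def _windows2(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N,H/2,W/2,4,C) non-overlapping 2x2 windows."""
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("spatial dims must be even for 2x2 pooling")
    v = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return v.reshape(n, h // 2, w // 2, 4, c)


class MaxPool2:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        win = _windows2(x)
        self._arg = win.argmax(axis=3)
        self._shape = x.shape
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        onehot = (
            np.arange(4)[None, None, None, :, None] == self._arg[:, :, :, None, :]
        )
        dwin = onehot * dy[:, :, :, None, :]
        dwin = dwin.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dwin.reshape(self._shape).astype(np.float32)


class AvgPool2:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return _windows2(x).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * 0.25
        return d.astype(np.float32)


class UpsampleNearest2:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return _windows2(dy).sum(axis=3)


def concat_channels(xs: list[np.ndarray]) -> np.ndarray:
    return np.concatenate(xs, axis=-1)


def split_channels(d: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    return np.split(d, np.cumsum(sizes)[:-1], axis=-1)


class Adam:
    """Adam with a mutable learning rate (for plateau decay)."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)  # list of (value, grad) array pairs
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
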