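"""Minimal NumPy layers with explicit forward/backward passes.

All tensors are float32 in NCHW layout.  Convolutions use zero 'same'
padding and im2col + BLAS matmul; each layer caches what its backward pass
needs, so a layer instance handles one forward/backward pair at a time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "Adam"]


class Conv2d:
    """k x k same-padding convolution with bias (k odd)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        # He initialization, appropriate for the ReLU blocks
        self.W = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.W + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        g = gout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        g = np.ascontiguousarray(g)
        self.gW += self._cols.T @ g
        self.gb += g.sum(axis=0)
        gcols = (g @ self.W.T).reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        gin = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for dy in range(k):
            for dx in range(k):
                gin[:, :, dy : dy + h, dx : dx + w] += gcols[:, :, :, :, dy, dx]
        self._cols = None
        return gin[:, :, p : p + h, p : p + w] if p else gin

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = self._mask * gout[:, :, :, None, :, None]
        return g.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            g[...] = 0.0
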