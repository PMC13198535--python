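"""Minimal 1-D convolutional building blocks with hand-written backprop.

Just enough machinery for the spindle segmenter: same-padded 1-D
convolutions (im2col + BLAS matmul), ReLU, max-pooling, nearest-neighbour
upsampling and an Adam optimizer.  Everything runs in float32 on the CPU and
is deterministic for a fixed seed.

Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np


class Conv1d:
    """Same-padded 1-D convolution (odd kernel size)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, n = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, C, N, K) view -> (B, N, C*K) matrix
        view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        cols = np.ascontiguousarray(view.transpose(0, 2, 1, 3)).reshape(b, n, c * k)
        w2 = self.w.reshape(self.w.shape[0], -1)  # (Cout, C*K)
        y = cols @ w2.T + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, n = self._in_shape
        k = self.kernel
        pad = k // 2
        dyt = dy.transpose(0, 2, 1)  # (B, N, Cout)
        c_out = self.w.shape[0]
        self.dw += (
            np.einsum("bnf,bno->of", self._cols, dyt, optimize=True)
            .reshape(c_out, c, k)
            .astype(np.float32)
        )
        self.db += dyt.sum(axis=(0, 1)).astype(np.float32)
        w2 = self.w.reshape(c_out, -1)
        dcols = (dyt @ w2).reshape(b, n, c, k)
        dxp = np.zeros((b, c, n + 2 * pad), dtype=np.float32)
        for j in range(k):
            dxp[:, :, j: j + n] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pad: pad + n]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def parameters(self):
        return []


class MaxPool1d:
    """Non-overlapping max pooling; input length must divide the factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, n = x.shape
        p = self.factor
        grouped = x.reshape(b, c, n // p, p)
        idx = grouped.argmax(axis=3)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(grouped, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, n = self._shape
        p = self.factor
        dx = np.zeros((b, c, n // p, p), dtype=np.float32)
        np.put_along_axis(dx, self._idx[..., None], dy[..., None], axis=3)
        return dx.reshape(b, c, n)

    def parameters(self):
        return []


class Upsample1d:
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, n = dy.shape
        p = self.factor
        return dy.reshape(b, c, n // p, p).sum(axis=3)

    def parameters(self):
        return []


class Adam:
    """Adam over a flat list of (param, grad) array pairs (updated in place)."""

    def __init__(self, params, lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of a (B, C, N) array."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
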