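"""Minimal 3-D convolutional network engine on numpy.

Implements exactly the pieces the E-field surrogate needs — 3-D convolution
(kernel 1 or 3, stride 1 or 2) via im2col GEMM, ReLU, nearest-neighbour
upsampling, residual blocks, channel concatenation and an Adam optimizer —
with hand-written backward passes. Everything is float32 and deterministic
given the initialization seed.

Layers follow a forward(x)/backward(dy) protocol; forward caches what backward
needs. Arrays are channels-LAST: (batch, nx, ny, nz, channels), which keeps
the im2col gather cache-friendly (each of the 27 taps reads a contiguous
channel run).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "ReLU", "Upsample2", "ResBlock", "Adam", "avg_pool",
           "he_init", "cosine_lr"]


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d:
    """k^3 convolution, same padding for k=3, stride 1 or 2.

    Weights are stored (k^3 * c_in, c_out) with tap-major, channel-minor row
    order, matching the im2col column order.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int = 3, stride: int = 1):
        if kernel not in (1, 3) or stride not in (1, 2):
            raise ValueError("supported: kernel in {1,3}, stride in {1,2}")
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        self.W = he_init(rng, c_in * kernel**3, (kernel**3 * c_in, c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        B, D, H, Wd, C = x.shape
        k, s = self.k, self.s
        if k == 3:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]  # (B, Do, Ho, Wo, C, k, k, k)
        B_, Do, Ho, Wo = win.shape[:4]
        # tap-major, channel-minor columns: (B*V, k^3*C)
        cols = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(
            B_ * Do * Ho * Wo, k**3 * C)
        return np.ascontiguousarray(cols), (B, Do, Ho, Wo, D, H, Wd)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, geom = self._im2col(x)
        B, Do, Ho, Wo, *_ = geom
        y = cols @ self.W + self.b
        if train:
            self._cache = (cols, geom)
        return y.reshape(B, Do, Ho, Wo, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (B, Do, Ho, Wo, D, H, Wd) = self._cache
        self._cache = None
        k, s = self.k, self.s
        dyf = dy.reshape(-1, self.c_out)
        self.dW += cols.T @ dyf
        self.db += dyf.sum(axis=0)
        dcols = dyf @ self.W.T  # (B*V, k^3*C)
        dvol = dcols.reshape(B, Do, Ho, Wo, k, k, k, self.c_in)
        pad = 1 if k == 3 else 0
        dxp = np.zeros((B, D + 2 * pad, H + 2 * pad, Wd + 2 * pad, self.c_in),
                       dtype=np.float32)
        for kz in range(k):
            for ky in range(k):
                for kx in range(k):
                    dxp[:,
                        kz:kz + s * Do:s,
                        ky:ky + s * Ho:s,
                        kx:kx + s * Wo:s] += dvol[:, :, :, :, kz, ky, kx]
        if pad:
            return dxp[:, 1:-1, 1:-1, 1:-1]
        return dxp


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return dy * m


class Upsample2:
    """Nearest-neighbour x2 upsampling in the three spatial axes."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, D, H, W, C = dy.shape
        return dy.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4, 6))


class ResBlock:
    """Two 3x3x3 convs with an identity skip: relu(conv(relu(conv(x))) + x)."""

    def __init__(self, rng: np.random.Generator, channels: int):
        self.c1 = Conv3d(rng, channels, channels)
        self.r1 = ReLU()
        self.c2 = Conv3d(rng, channels, channels)
        self.r_out = ReLU()

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.r1.forward(self.c1.forward(x, train), train)
        return self.r_out.forward(self.c2.forward(h, train) + x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.r_out.backward(dy)
        dx = self.c1.backward(self.r1.backward(self.c2.backward(d)))
        return dx + d


def avg_pool(x: np.ndarray, factor: int) -> np.ndarray:
    """Average pooling by an integer factor over the three spatial axes."""
    B, D, H, W, C = x.shape
    f = factor
    return x.reshape(B, D // f, f, H // f, f, W // f, f, C).mean(axis=(2, 4, 6))


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def cosine_lr(step: int, total_steps: int, base_lr: float, warmup_frac: float) -> float:
    """Linear warmup over the first ``warmup_frac`` of steps, then cosine decay to 0."""
    warm = max(int(round(warmup_frac * total_steps)), 1)
    if step < warm:
        return base_lr * (step + 1) / warm
    prog = (step - warm) / max(total_steps - warm, 1)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * prog))
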