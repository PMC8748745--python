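"""Minimal numpy building blocks for the 3D segmentation network.

Convolutions run as im2col + BLAS matrix products in float32, with explicit
backward passes; this keeps the whole training loop dependency-free and
deterministic for a fixed seed on one device. Only the handful of layer
types the network needs are implemented: 3D convolution (kernel 1 or 3,
stride 1 or 2, zero padding), ReLU, nearest-neighbor 2x upsampling,
high-index-edge trimming, channel concatenation, channel softmax, and Adam.

Feature maps are float32 arrays of shape (C, Z, Y, X); batching is done by
gradient accumulation over samples.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "relu", "relu_backward", "upsample2", "upsample2_backward",
           "trim_to", "trim_backward", "softmax_channels", "softmax_backward", "Adam"]


class Conv3d:
    """3D convolution with zero padding ``k // 2`` (shape-preserving at stride 1).

    Weights use He-normal initialization. ``forward`` caches the im2col
    matrix for the subsequent ``backward``, which accumulates ``dW``/``db``
    and returns the gradient w.r.t. the input.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if k not in (1, 3) or stride not in (1, 2):
            raise ValueError("supported: kernel 1 or 3, stride 1 or 2")
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        fan_in = cin * k**3
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        view = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
        out_shape = view.shape[1:4]
        cols = np.ascontiguousarray(view.transpose(0, 4, 5, 6, 1, 2, 3)).reshape(
            self.cin * k**3, -1
        )
        return cols, out_shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, out_shape = self._im2col(x.astype(np.float32, copy=False))
        y = self.W @ cols + self.b[:, None]
        if train:
            self._cache = (cols, x.shape[1:], out_shape)
        return y.reshape((self.cout,) + out_shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, in_shape, out_shape = self._cache
        self._cache = None
        dyf = dy.reshape(self.cout, -1).astype(np.float32, copy=False)
        self.dW += dyf @ cols.T
        self.db += dyf.sum(axis=1)
        dcols = (self.W.T @ dyf).reshape((self.cin,) + (self.k,) * 3 + out_shape)
        k, s, p = self.k, self.stride, self.pad
        padded = np.zeros(
            (self.cin, in_shape[0] + 2 * p, in_shape[1] + 2 * p, in_shape[2] + 2 * p),
            dtype=np.float32,
        )
        zo, yo, xo = out_shape
        for dz in range(k):
            for dyy in range(k):
                for dxx in range(k):
                    padded[:, dz:dz + s * zo:s, dyy:dyy + s * yo:s, dxx:dxx + s * xo:s] += (
                        dcols[:, dz, dyy, dxx]
                    )
        if p:
            return padded[:, p:-p, p:-p, p:-p]
        return padded


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor 2x upsampling of each spatial axis."""
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, z, y, x = dy.shape
    return dy.reshape(c, z // 2, 2, y // 2, 2, x // 2, 2).sum(axis=(2, 4, 6))


def trim_to(x: np.ndarray, spatial: tuple[int, int, int]) -> np.ndarray:
    """Remove extra voxels on the high-index edge so shapes match a skip map."""
    return x[:, : spatial[0], : spatial[1], : spatial[2]]


def trim_backward(dy: np.ndarray, spatial: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros((dy.shape[0],) + spatial, dtype=dy.dtype)
    out[:, : dy.shape[1], : dy.shape[2], : dy.shape[3]] = dy
    return out


def softmax_channels(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * (dy - (dy * y).sum(axis=0, keepdims=True))


class Adam:
    """Adam over a list of Conv3d layers (decoupled from the architecture)."""

    def __init__(self, layers: list[Conv3d], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [
            (np.zeros_like(l.W), np.zeros_like(l.W), np.zeros_like(l.b), np.zeros_like(l.b))
            for l in layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for layer, (mW, vW, mb, vb) in zip(self.layers, self.state):
            for param, grad, m, v in ((layer.W, layer.dW, mW, vW), (layer.b, layer.db, mb, vb)):
                m += (1 - b1) * (grad - m)
                v += (1 - b2) * (grad * grad - v)
                param -= self.lr * corr * m / (np.sqrt(v) + self.eps)
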