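"""Minimal NumPy building blocks for convolutional encoder-decoder nets.

Implements exactly the pieces the segmentation network needs: same-padded
2-D convolution, ReLU, 2x2 max pooling, nearest-neighbor upsampling, softmax
cross-entropy, and Adam. Tensors are (N, C, H, W) float32. Gradients are
computed layer-by-layer with cached forward inputs; convolution backward
uses the adjoint convolution with the spatially flipped, transposed kernel
(valid for stride 1 with same padding).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padding correlation of x (N,C,H,W) with w (O,C,k,k)."""
    k = w.shape[-1]
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


class Conv2D:
    """k x k convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * ksize * ksize))
        self.w = (rng.standard_normal((c_out, c_in, ksize, ksize)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        out = _conv_same(x, self.w)
        out += self.b[None, :, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        k = self.w.shape[-1]
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.dw = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3])).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        w_adj = self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        dx = _conv_same(dy, np.ascontiguousarray(w_adj))
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling with stride 2; H and W must be even."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = x6.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dx.reshape(n, c, h, w))

    def params(self):
        return []


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Mean pixelwise cross-entropy and its gradient w.r.t. the logits.

    logits: (N, K, H, W) float; target: (N, H, W) int class indices.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    # per-pixel probability of the true class
    pt = np.take_along_axis(p, target[:, None, :, :], axis=1)[:, 0]
    loss = float(-np.log(np.clip(pt, 1e-12, None)).mean())
    dlogits = p.copy()
    np.put_along_axis(
        dlogits,
        target[:, None, :, :],
        np.take_along_axis(dlogits, target[:, None, :, :], axis=1) - 1.0,
        axis=1,
    )
    dlogits /= n * h * w
    return loss, dlogits.astype(np.float32)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        """params: iterable of (array, grad) pairs; arrays updated in place."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for w, g in params:
            key = id(w)
            m = self._m.setdefault(key, np.zeros_like(w))
            v = self._v.setdefault(key, np.zeros_like(w))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            w -= self.lr * mh / (np.sqrt(vh) + self.eps)
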