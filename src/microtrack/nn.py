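"""Minimal CPU convolutional-network core.

Implements exactly the pieces a U-Net needs — 'same' 3x3 and 1x1
convolutions (im2col + BLAS matmul), ReLU, 2x2 max pooling, 2x nearest
upsampling, channel concatenation, a sigmoid head — together with their
analytic gradients and an Adam optimiser.  Everything is plain numpy in
NCHW layout; the finite-difference tests in the suite pin the gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv3x3", "conv3x3_backward", "conv1x1", "conv1x1_backward",
    "relu", "relu_backward", "maxpool2", "maxpool2_backward",
    "upsample2", "upsample2_backward", "sigmoid", "Adam", "he_init",
]


def he_init(rng: np.random.Generator, c_out: int, c_in: int, k: int,
            dtype=np.float32) -> np.ndarray:
    """He-normal initialisation for a (c_out, c_in*k*k) kernel matrix."""
    fan_in = c_in * k * k
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
    return w.astype(dtype)


def _im2col3(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


def conv3x3(x: np.ndarray, wmat: np.ndarray, b: np.ndarray | None):
    """'Same' 3x3 convolution.  ``wmat`` is (C_out, C_in*9).

    Returns (out, cols); ``cols`` is the im2col cache for the backward pass.
    """
    n, c, h, w = x.shape
    cols = _im2col3(x)
    out = cols @ wmat.T
    if b is not None:
        out += b
    c_out = wmat.shape[0]
    return out.reshape(n, h, w, c_out).transpose(0, 3, 1, 2), cols


def conv3x3_backward(gout: np.ndarray, cols: np.ndarray, wmat: np.ndarray,
                     c_in: int):
    """Gradients of a 'same' 3x3 conv: (dx, dwmat, db)."""
    n, c_out, h, w = gout.shape
    g = gout.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
    dw = g.T @ cols
    db = g.sum(axis=0)
    # dx is the 'full' correlation of gout with the flipped, channel-swapped
    # kernel, which for same-padding 3x3 stride-1 is again a same-conv.
    wk = wmat.reshape(c_out, c_in, 3, 3)
    wb = wk.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1].reshape(c_in, c_out * 9)
    dx, _ = conv3x3(gout, np.ascontiguousarray(wb), None)
    return dx, dw, db


def conv1x1(x: np.ndarray, wmat: np.ndarray, b: np.ndarray | None):
    n, c, h, w = x.shape
    cols = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
    out = cols @ wmat.T
    if b is not None:
        out += b
    return out.reshape(n, h, w, wmat.shape[0]).transpose(0, 3, 1, 2), cols


def conv1x1_backward(gout: np.ndarray, cols: np.ndarray, wmat: np.ndarray):
    n, c_out, h, w = gout.shape
    g = gout.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
    dw = g.T @ cols
    db = g.sum(axis=0)
    dx = (g @ wmat).reshape(n, h, w, wmat.shape[1]).transpose(0, 3, 1, 2)
    return dx, dw, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(gout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, gout, 0.0)


def maxpool2(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    return out, x


def maxpool2_backward(gout: np.ndarray, x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    mx = gout.reshape(n, c, h // 2, 1, w // 2, 1)
    mask = xr == xr.max(axis=(3, 5), keepdims=True)
    # split the gradient among ties so it stays exact for the loss
    counts = mask.sum(axis=(3, 5), keepdims=True)
    return (mask * (mx / counts)).reshape(n, c, h, w)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(gout: np.ndarray) -> np.ndarray:
    n, c, h, w = gout.shape
    return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for k, g in grads.items():
            p = params[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= (self.lr * corr * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
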