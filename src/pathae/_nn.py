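"""Shared numerical kernels: same-padded convolution, 2x2 pooling/unpooling,
sigmoid, softmax and an Adam optimizer, with hand-derived backward passes.

All image-like arrays are channels-last: a single image is (H, W, C) and a
batch is (B, H, W, C). Convolution weights are (f, f, C_in, C_out).
Same padding for filter size f pads (f-1)//2 before and f//2 after each
spatial axis, so output spatial dims always equal input spatial dims.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ShapeError",
    "DataError",
    "ConfigError",
    "CheckpointError",
    "sigmoid",
    "softmax",
    "log_softmax",
    "conv2d_same",
    "conv2d_same_backward",
    "maxpool2",
    "maxpool2_backward",
    "unpool2",
    "unpool2_backward",
    "uniform_fanin_init",
    "Adam",
]


class ShapeError(ValueError):
    """Array dimensions violate an operation's contract."""


class DataError(ValueError):
    """Dataset is empty, degenerate or otherwise unusable."""


class ConfigError(ValueError):
    """Configuration value or key is invalid."""


class CheckpointError(RuntimeError):
    """Checkpoint file is missing, corrupt or of an incompatible version."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def _pad_same(x: np.ndarray, f: int) -> tuple[np.ndarray, int]:
    pl, pr = (f - 1) // 2, f // 2
    return np.pad(x, ((0, 0), (pl, pr), (pl, pr), (0, 0))), pl


def _windows(xp: np.ndarray, f: int) -> np.ndarray:
    # (B, H, W, C, f, f) view, no copy
    return np.lib.stride_tricks.sliding_window_view(xp, (f, f), axis=(1, 2))


def _im2col(x: np.ndarray, f: int) -> np.ndarray:
    """(B*H*W, f*f*C) patch matrix in (u, v, c) column order."""
    xp, _ = _pad_same(x, f)
    win = _windows(xp, f)  # (B, H, W, C, f, f)
    B, H, W, C = x.shape
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(B * H * W, f * f * C)


def conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Same-padded 2-D cross-correlation of a batch with a filter bank."""
    f, _, C, F = w.shape
    B, H, W, _ = x.shape
    out = (_im2col(x, f) @ w.reshape(f * f * C, F)).reshape(B, H, W, F)
    if b is not None:
        out = out + b
    return out


def conv2d_same_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dW, db, dX) of conv2d_same given upstream gradient dout."""
    f, _, C, F = w.shape
    B, H, W, _ = x.shape
    dflat = dout.reshape(B * H * W, F)
    dw = (_im2col(x, f).T @ dflat).reshape(f, f, C, F)
    db = dflat.sum(axis=0)
    pl = (f - 1) // 2
    dxp = np.zeros((B, H + f - 1, W + f - 1, C))
    for u in range(f):
        for v in range(f):
            dxp[:, u : u + H, v : v + W, :] += (dflat @ w[u, v].T).reshape(B, H, W, C)
    dx = dxp[:, pl : pl + H, pl : pl + W, :]
    return dw, db, dx


def maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 non-overlapping max pooling; spatial dims must be even."""
    B, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ShapeError(f"spatial dims must be divisible by 2, got {H}x{W}")
    return x.reshape(B, H // 2, 2, W // 2, 2, C).max(axis=(2, 4))


def maxpool2_backward(x: np.ndarray, pooled: np.ndarray, dout: np.ndarray) -> np.ndarray:
    """Route gradient to the max location(s); ties share the gradient equally."""
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
    mask = xr == pooled[:, :, None, :, None, :]
    cnt = mask.sum(axis=(2, 4), keepdims=True)
    g = mask * (dout[:, :, None, :, None, :] / cnt)
    return g.reshape(B, H, W, C)


def unpool2(z: np.ndarray) -> np.ndarray:
    """Copy each value into a 2x2 block (no pooling switches)."""
    return np.repeat(np.repeat(z, 2, axis=1), 2, axis=2)


def unpool2_backward(dout: np.ndarray) -> np.ndarray:
    B, H, W, C = dout.shape
    return dout.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def uniform_fanin_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with the standard bias-corrected moment estimates.

    Parameters are held in a name->array dict and updated in place.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
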