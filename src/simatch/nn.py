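"""Minimal neural-network primitives on autograd + numpy.

Forward passes are pure functions of a parameter dict (name -> float32
array); gradients come from reverse-mode differentiation via ``autograd``.
Convolutions are evaluated as gather (im2col) + matmul with cached index
arrays, which keeps the arithmetic in BLAS; max-pooling is a reshape + max.
This is deliberately small: just what the three-stream encoders need
(1D/3D convolution, max-pooling, spatial dropout, a single-layer LSTM, a
dense projection, and an Adam optimizer).
"""

from __future__ import annotations

from itertools import product

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive

DTYPE = np.float32


# ---------------------------------------------------------------------------
# convolution
#
# Implemented as an autograd primitive with hand-written vector-Jacobian
# products so that both directions run as strided-slice data movement plus
# one BLAS matmul (autograd's generic gather gradient is a scatter-add that
# dominates runtime otherwise).


def _out_shape(spatial: tuple[int, ...], k: int, stride: int, pad: int) -> tuple[int, ...]:
    out = tuple((s + 2 * pad - k) // stride + 1 for s in spatial)
    if any(o < 1 for o in out):
        raise ValueError(f"kernel {k} does not fit input {spatial} with pad {pad}")
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, *spatial) -> (B, C*K, P) columns, K = k^nd kernel taps."""
    nd = x.ndim - 2
    xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    out = _out_shape(x.shape[2:], k, stride, pad)
    B, C = x.shape[:2]
    taps = list(product(range(k), repeat=nd))
    cols = np.empty((B, C, len(taps)) + out, dtype=x.dtype)
    for j, tap in enumerate(taps):
        sl = tuple(slice(o, o + (n - 1) * stride + 1, stride) for o, n in zip(tap, out))
        cols[:, :, j] = xp[(slice(None), slice(None)) + sl]
    return cols.reshape(B, C * len(taps), -1)


def _col2im(
    dcols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of _im2col: scatter columns back, summing overlaps."""
    nd = len(x_shape) - 2
    B, C = x_shape[:2]
    out = _out_shape(x_shape[2:], k, stride, pad)
    taps = list(product(range(k), repeat=nd))
    dcols = dcols.reshape((B, C, len(taps)) + out)
    xp = np.zeros((B, C) + tuple(s + 2 * pad for s in x_shape[2:]), dtype=dcols.dtype)
    for j, tap in enumerate(taps):
        sl = tuple(slice(o, o + (n - 1) * stride + 1, stride) for o, n in zip(tap, out))
        xp[(slice(None), slice(None)) + sl] += dcols[:, :, j]
    unpad = tuple(slice(pad, sp + pad) for sp in x_shape[2:])
    return xp[(slice(None), slice(None)) + unpad]


@primitive
def _conv(x, w, b, stride: int, pad: int):
    k = w.shape[2]
    out = _out_shape(x.shape[2:], k, stride, pad)
    cols = _im2col(x, k, stride, pad)  # (B, C*K, P)
    wmat = w.reshape(w.shape[0], -1)  # (F, C*K)
    y = np.matmul(wmat, cols) + b[:, None]  # (B, F, P)
    return y.reshape((x.shape[0], w.shape[0]) + out)


def _conv_vjp_x(ans, x, w, b, stride, pad):
    def vjp(g):
        B, F = g.shape[:2]
        gy = g.astype(w.dtype, copy=False).reshape(B, F, -1)  # (B, F, P)
        dcols = np.matmul(w.reshape(F, -1).T, gy)  # (B, C*K, P)
        return _col2im(dcols, x.shape, w.shape[2], stride, pad)

    return vjp


def _conv_vjp_w(ans, x, w, b, stride, pad):
    def vjp(g):
        B, F = g.shape[:2]
        gy = g.astype(x.dtype, copy=False).reshape(B, F, -1)  # (B, F, P)
        cols = _im2col(x, w.shape[2], stride, pad)  # (B, C*K, P)
        dw = np.zeros((F, cols.shape[1]), dtype=x.dtype)
        for i in range(B):  # per-sample GEMMs avoid large transposed copies
            dw += gy[i] @ cols[i].T
        return dw.reshape(w.shape)

    return vjp


def _conv_vjp_b(ans, x, w, b, stride, pad):
    def vjp(g):
        return g.reshape(g.shape[0], g.shape[1], -1).sum(axis=(0, 2))

    return vjp


defvjp(_conv, _conv_vjp_x, _conv_vjp_w, _conv_vjp_b)


def conv_nd(x, w, b, stride: int = 1, pad: int | None = None):
    """N-dimensional convolution (N = 1 or 3 here).

    x : (B, C, *spatial); w : (F, C, *[k]*N); b : (F,)
    'same'-style zero padding of k // 2 by default.
    """
    if pad is None:
        pad = w.shape[2] // 2
    return _conv(x, w, b, stride, pad)


# ---------------------------------------------------------------------------
# pooling and activations


@primitive
def _pool_axis(x, axis: int, p: int):
    n = x.shape[axis]
    if n < p:
        return x
    m = n // p
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, m * p)
    xr = x[tuple(sl)].reshape(x.shape[:axis] + (m, p) + x.shape[axis + 1 :])
    return xr.max(axis=axis + 1)


def _pool_axis_vjp(ans, x, axis, p):
    def vjp(g):
        n = x.shape[axis]
        if n < p:
            return np.asarray(g)
        m = n // p
        sl = [slice(None)] * x.ndim
        sl[axis] = slice(0, m * p)
        xr = x[tuple(sl)].reshape(x.shape[:axis] + (m, p) + x.shape[axis + 1 :])
        idx = xr.argmax(axis=axis + 1, keepdims=True)
        dxr = np.zeros_like(xr)
        np.put_along_axis(
            dxr, idx, np.expand_dims(g, axis + 1).astype(x.dtype, copy=False), axis=axis + 1
        )
        dx = np.zeros_like(x)
        dx[tuple(sl)] = dxr.reshape(dx[tuple(sl)].shape)
        return dx

    return vjp


defvjp(_pool_axis, _pool_axis_vjp)


@primitive
def _axis_max(x, axis: int):
    return x.max(axis=axis)


def _axis_max_vjp(ans, x, axis):
    def vjp(g):
        idx = np.expand_dims(x.argmax(axis=axis), axis)
        dx = np.zeros_like(x)
        np.put_along_axis(dx, idx, np.expand_dims(g, axis).astype(x.dtype, copy=False), axis=axis)
        return dx

    return vjp


defvjp(_axis_max, _axis_max_vjp)


def maxpool(x, axes: tuple[int, ...], p: int = 2):
    """Max-pool with window/stride ``p`` along each listed axis (axes whose
    extent is already < p are left untouched; a ragged tail is dropped)."""
    for ax in axes:
        x = _pool_axis(x, ax, p)
    return x


def global_maxpool(x, axes: tuple[int, ...]):
    for ax in sorted(axes, reverse=True):
        x = _axis_max(x, ax)
    return x


@primitive
def relu(x):
    return np.maximum(x, 0.0)


defvjp(relu, lambda ans, x: lambda g: np.asarray(g) * (x > 0))


def sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def spatial_dropout(x, mask):
    """Multiply by a precomputed per-channel keep mask (None = identity)."""
    if mask is None:
        return x
    return x * mask


def make_channel_mask(
    rng: np.random.Generator, batch: int, channels: int, rate: float, nd: int
) -> np.ndarray:
    """Inverted-dropout mask zeroing whole channels with probability ``rate``."""
    keep = (rng.random((batch, channels)) >= rate).astype(DTYPE) / DTYPE(1.0 - rate)
    return keep.reshape((batch, channels) + (1,) * nd)


# ---------------------------------------------------------------------------
# LSTM and dense


def lstm(x, wx, wh, b):
    """Single-layer LSTM over (B, T, D) input; returns the final hidden state."""
    B, T, _ = x.shape
    H = wh.shape[0]
    h = anp.zeros((B, H), dtype=DTYPE)
    c = anp.zeros((B, H), dtype=DTYPE)
    for t in range(T):
        z = anp.matmul(x[:, t, :], wx) + anp.matmul(h, wh) + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        o = sigmoid(z[:, 2 * H : 3 * H])
        g = anp.tanh(z[:, 3 * H :])
        c = f * c + i * g
        h = o * anp.tanh(c)
    return h


def dense(x, w, b):
    return anp.matmul(x, w) + b


# ---------------------------------------------------------------------------
# initialization


def init_conv(rng: np.random.Generator, f: int, c: int, k: int, nd: int) -> np.ndarray:
    fan_in = c * k**nd
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=(f, c) + (k,) * nd).astype(DTYPE)


def init_dense(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (d_in + d_out))
    return rng.normal(0.0, std, size=(d_in, d_out)).astype(DTYPE)


def init_lstm(rng: np.random.Generator, d_in: int, h: int) -> dict[str, np.ndarray]:
    wx = init_dense(rng, d_in, 4 * h)
    wh = init_dense(rng, h, 4 * h)
    b = np.zeros(4 * h, dtype=DTYPE)
    b[h : 2 * h] = 1.0  # forget-gate bias
    return {"wx": wx, "wh": wh, "b": b}


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = (params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
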