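"""Numerical checks of the autograd primitives against oracles.

Convolution is compared with scipy.signal.correlate; every custom
vector-Jacobian product is checked against central finite differences.
"""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad
from scipy import signal

from simatch import nn


def _fd_grad(f, x, eps=1e-3):
    """Central finite-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.astype(float).copy()
        xm = x.astype(float).copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp.astype(x.dtype)) - f(xm.astype(x.dtype))) / (2 * eps)
    return g


def _scipy_conv_ref(x, w, b, pad):
    """Oracle: cross-correlation per (batch, filter), summed over channels."""
    B, C = x.shape[:2]
    F = w.shape[0]
    nd = x.ndim - 2
    xp = np.pad(x.astype(float), [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    out = None
    for i in range(B):
        for f in range(F):
            acc = sum(
                signal.correlate(xp[i, c], w[f, c].astype(float), mode="valid")
                for c in range(C)
            ) + b[f]
            if out is None:
                out = np.zeros((B, F) + acc.shape)
            out[i, f] = acc
    return out


@pytest.mark.parametrize("nd,shape", [(1, (7,)), (3, (5, 6, 4))])
def test_conv_matches_scipy(nd, shape):
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 3) + shape).astype(nn.DTYPE)
    w = rng.normal(size=(4, 3) + (3,) * nd).astype(nn.DTYPE)
    b = rng.normal(size=4).astype(nn.DTYPE)
    y = nn.conv_nd(x, w, b)  # same padding (pad=1)
    ref = _scipy_conv_ref(x, w, b, pad=1)
    assert y.shape == ref.shape == (2, 4) + shape
    np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-4)


def test_conv_stride_and_no_pad():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, 2, 9)).astype(nn.DTYPE)
    w = rng.normal(size=(3, 2, 3)).astype(nn.DTYPE)
    b = np.zeros(3, dtype=nn.DTYPE)
    y = nn.conv_nd(x, w, b, stride=2, pad=0)
    assert y.shape == (1, 3, 4)  # (9 - 3) // 2 + 1
    ref = _scipy_conv_ref(x, w, b, pad=0)[:, :, ::2]
    np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-4)


def test_conv_kernel_too_large():
    x = np.zeros((1, 1, 2), dtype=nn.DTYPE)
    w = np.zeros((1, 1, 7), dtype=nn.DTYPE)
    with pytest.raises(ValueError, match="does not fit"):
        nn.conv_nd(x, w, np.zeros(1, dtype=nn.DTYPE), pad=0)


@pytest.mark.parametrize("wrt", [0, 1, 2])  # x, w, b
def test_conv_grads_finite_difference(wrt):
    rng = np.random.default_rng(2)
    x = rng.normal(size=(2, 2, 6)).astype(nn.DTYPE)
    w = rng.normal(size=(3, 2, 3)).astype(nn.DTYPE)
    b = rng.normal(size=3).astype(nn.DTYPE)
    args = [x, w, b]
    proj = rng.normal(size=(2, 3, 6)).astype(nn.DTYPE)  # fixed cotangent

    def loss(v):
        a = list(args)
        a[wrt] = v
        return anp.sum(nn.conv_nd(a[0], a[1], a[2]) * proj)

    ag = grad(loss)(args[wrt])
    fd = _fd_grad(lambda v: float(loss(v)), args[wrt])
    np.testing.assert_allclose(ag, fd, rtol=2e-2, atol=2e-2)


def test_conv3d_grad_x_finite_difference():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(1, 1, 4, 4, 3)).astype(nn.DTYPE)
    w = rng.normal(size=(2, 1, 3, 3, 3)).astype(nn.DTYPE)
    b = np.zeros(2, dtype=nn.DTYPE)
    proj = rng.normal(size=(1, 2, 4, 4, 3)).astype(nn.DTYPE)

    def loss(v):
        return anp.sum(nn.conv_nd(v, w, b) * proj)

    np.testing.assert_allclose(
        grad(loss)(x), _fd_grad(lambda v: float(loss(v)), x), rtol=2e-2, atol=2e-2
    )


def test_maxpool_forward():
    x = np.arange(10, dtype=nn.DTYPE).reshape(1, 1, 10)
    y = nn.maxpool(x, axes=(2,))
    np.testing.assert_array_equal(np.asarray(y)[0, 0], [1, 3, 5, 7, 9])
    # ragged tail dropped: 5 -> 2 windows
    y2 = nn.maxpool(np.arange(5, dtype=nn.DTYPE).reshape(1, 1, 5), axes=(2,))
    np.testing.assert_array_equal(np.asarray(y2)[0, 0], [1, 3])
    # axis shorter than the window is untouched
    y3 = nn.maxpool(np.ones((1, 1, 1), dtype=nn.DTYPE), axes=(2,))
    assert np.asarray(y3).shape == (1, 1, 1)


def test_maxpool_grad_finite_difference():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(2, 3, 7)).astype(nn.DTYPE)
    proj = rng.normal(size=(2, 3, 3)).astype(nn.DTYPE)

    def loss(v):
        return anp.sum(nn.maxpool(v, axes=(2,)) * proj)

    np.testing.assert_allclose(
        grad(loss)(x), _fd_grad(lambda v: float(loss(v)), x), rtol=2e-2, atol=2e-2
    )


def test_global_maxpool_and_grad():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(2, 4, 5, 3)).astype(nn.DTYPE)
    y = nn.global_maxpool(x, axes=(2, 3))
    np.testing.assert_allclose(np.asarray(y), x.max(axis=(2, 3)), rtol=1e-6)
    proj = rng.normal(size=(2, 4)).astype(nn.DTYPE)

    def loss(v):
        return anp.sum(nn.global_maxpool(v, axes=(2, 3)) * proj)

    np.testing.assert_allclose(
        grad(loss)(x), _fd_grad(lambda v: float(loss(v)), x), rtol=2e-2, atol=2e-2
    )


def test_relu_grad():
    x = np.array([-1.0, -0.1, 0.5, 2.0], dtype=nn.DTYPE)
    g = grad(lambda v: anp.sum(nn.relu(v) * np.array([1.0, 2.0, 3.0, 4.0], dtype=nn.DTYPE)))(x)
    np.testing.assert_allclose(g, [0.0, 0.0, 3.0, 4.0])


def test_dropout_mask_scaling():
    rng = np.random.default_rng(0)
    mask = nn.make_channel_mask(rng, batch=200, channels=16, rate=0.25, nd=2)
    assert mask.shape == (200, 16, 1, 1)
    vals = np.unique(mask)
    np.testing.assert_allclose(sorted(vals), [0.0, 1 / 0.75], rtol=1e-6)
    # inverted dropout keeps the expectation ~1
    np.testing.assert_allclose(mask.mean(), 1.0, atol=0.05)
    x = np.ones((200, 16, 4), dtype=nn.DTYPE)
    assert nn.spatial_dropout(x, None) is x


def test_lstm_shapes_and_grad_flow():
    rng = np.random.default_rng(0)
    p = nn.init_lstm(rng, d_in=5, h=8)
    x = rng.normal(size=(3, 6, 5)).astype(nn.DTYPE)
    h = nn.lstm(x, p["wx"], p["wh"], p["b"])
    assert np.asarray(h).shape == (3, 8)
    g = grad(lambda w: anp.sum(nn.lstm(x, w, p["wh"], p["b"]) ** 2))(p["wx"])
    assert np.abs(g).sum() > 0


def test_adam_converges_on_quadratic():
    params = {"w": np.array([5.0, -3.0], dtype=nn.DTYPE)}
    opt = nn.Adam(params, lr=0.1)
    for _ in range(300):
        opt.step(params, {"w": 2 * params["w"]})  # d/dw of ||w||^2
    assert np.abs(params["w"]).max() < 1e-2


def test_init_conv_he_scale():
    rng = np.random.default_rng(0)
    w = nn.init_conv(rng, f=64, c=32, k=3, nd=3)
    assert w.shape == (64, 32, 3, 3, 3) and w.dtype == nn.DTYPE
    np.testing.assert_allclose(w.std(), np.sqrt(2.0 / (32 * 27)), rtol=0.05)
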