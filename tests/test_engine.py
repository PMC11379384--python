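"""Unit tests for the autodiff engine: forward oracles and exact gradients."""

import numpy as np
import pytest

from manet.engine import functional as F
from manet.engine import (Adam, BatchNorm2d, Conv2d, Tensor, concat, no_grad,
                          seeded_init)

from conftest import check_grads, tensor64


def conv_loop_oracle(x, w, b, stride, dilation, padding):
    """Direct quadruple-loop cross-correlation."""
    N, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    Ho = (H + 2 * padding - eh) // stride + 1
    Wo = (W + 2 * padding - ew) // stride + 1
    y = np.zeros((N, O, Ho, Wo))
    for n in range(N):
        for o in range(O):
            for h in range(Ho):
                for v in range(Wo):
                    acc = 0.0
                    for c in range(C):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (xp[n, c, h * stride + i * dilation,
                                           v * stride + j * dilation] * w[o, c, i, j])
                    y[n, o, h, v] = acc + (b[o] if b is not None else 0.0)
    return y


@pytest.mark.parametrize("stride,dilation,padding", [(1, 1, 1), (2, 1, 1), (1, 2, 2),
                                                     (1, 3, 3), (2, 1, 0)])
def test_conv2d_matches_direct_loop(rng, stride, dilation, padding):
    x = rng.standard_normal((2, 3, 8, 8))
    w = rng.standard_normal((4, 3, 3, 3))
    b = rng.standard_normal(4)
    out = F.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=stride,
                   dilation=dilation, padding=padding)
    np.testing.assert_allclose(out.data, conv_loop_oracle(x, w, b, stride, dilation,
                                                          padding), atol=1e-10)


@pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 2)])
def test_conv2d_gradients(rng, stride, dilation):
    x = tensor64(rng, 2, 2, 6, 6)
    w = tensor64(rng, 3, 2, 3, 3)
    b = tensor64(rng, 3)
    check_grads(lambda: (F.conv2d(x, w, b, stride=stride, dilation=dilation,
                                  padding=dilation).sigmoid()).mean(), [x, w, b])


@pytest.mark.parametrize("kernel", [2, 3])
def test_conv_transpose_doubles_and_gradients(rng, kernel):
    pad, opad = (1, 1) if kernel == 3 else (0, 0)
    x = tensor64(rng, 2, 3, 4, 4)
    w = tensor64(rng, 3, 2, kernel, kernel)
    b = tensor64(rng, 2)
    out = F.conv_transpose2d(x, w, b, stride=2, padding=pad, output_padding=opad)
    assert out.shape == (2, 2, 8, 8)
    check_grads(lambda: (F.conv_transpose2d(x, w, b, stride=2, padding=pad,
                                            output_padding=opad) ** 2).mean(),
                [x, w, b])


def test_conv_transpose_is_adjoint_of_strided_conv(rng):
    """<conv(a), b> == <a, conv_transpose(b)> with shared (transposed) weights."""
    w = rng.standard_normal((5, 3, 3, 3))  # (O, C, kh, kw) for the forward conv
    a = rng.standard_normal((1, 3, 8, 8))
    bb = rng.standard_normal((1, 5, 4, 4))
    conv_ab = F.conv2d(Tensor(a), Tensor(w), stride=2, padding=1).data
    # transpose-conv weights are laid out (C_in, C_out, kh, kw) = w as-is here
    adj = F.conv_transpose2d(Tensor(bb), Tensor(w.copy()), stride=2, padding=1,
                             output_padding=1).data
    lhs = float((conv_ab * bb).sum())
    rhs = float((a * adj).sum())
    assert lhs == pytest.approx(rhs, rel=1e-10)


@pytest.mark.parametrize("kernel", [2, 3])
def test_max_pool_matches_block_reduce(rng, kernel):
    from skimage.measure import block_reduce

    x = rng.standard_normal((2, 3, 7, 7))
    out = F.max_pool2d(Tensor(x), kernel).data
    Ho = 7 // kernel
    expected = block_reduce(x[:, :, :Ho * kernel, :Ho * kernel],
                            (1, 1, kernel, kernel), np.max)
    np.testing.assert_array_equal(out, expected)


def test_max_pool_gradients(rng):
    x = tensor64(rng, 1, 2, 6, 6)
    check_grads(lambda: (F.max_pool2d(x, 3) ** 2).mean(), [x])


def test_batch_norm_train_normalizes_and_gradients(rng):
    x = tensor64(rng, 4, 3, 5, 5)
    bn = BatchNorm2d(3)
    g = Tensor(np.asarray(bn.gamma.data, dtype=np.float64), requires_grad=True)
    b = Tensor(np.asarray(bn.beta.data, dtype=np.float64), requires_grad=True)
    rm = np.zeros(3)
    rv = np.ones(3)
    out = F.batch_norm(x, g, b, rm.copy(), rv.copy(), training=True)
    np.testing.assert_allclose(out.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.data.var(axis=(0, 2, 3)), 1.0, atol=1e-4)

    def f():
        return (F.batch_norm(x, g, b, rm.copy(), rv.copy(),
                             training=True).sigmoid()).mean()

    check_grads(f, [x, g, b], rtol=1e-3)

    def f_eval():
        return (F.batch_norm(x, g, b, rm, rv, training=False) ** 2).mean()

    check_grads(f_eval, [x, g, b], rtol=1e-3)


def test_bilinear_resize_known_weights_and_gradients(rng):
    # 2 -> 4 with half-pixel centers: frozen interpolation rows
    x = Tensor(np.array([[[[0.0, 1.0], [2.0, 3.0]]]]))
    out = F.bilinear_resize(x, (4, 2)).data[0, 0, :, 0]
    np.testing.assert_allclose(out, [0.0, 0.5, 1.5, 2.0])
    # constant maps stay constant (row-stochastic weights)
    c = Tensor(np.full((1, 2, 5, 7), 3.25))
    np.testing.assert_allclose(F.bilinear_resize(c, (11, 4)).data, 3.25)
    xg = tensor64(rng, 1, 2, 3, 3)
    check_grads(lambda: (F.bilinear_resize(xg, (6, 6)).sigmoid()).mean(), [xg])


def test_elementwise_chain_gradients(rng):
    x = tensor64(rng, 3, 4)
    y = tensor64(rng, 3, 4)

    def f():
        p = (x * 0.3 + y.sigmoid()).clip(0.05, 0.95)
        return -(p.log() + (1.0 - p).log()).mean() / (1.0 + (x ** 2).mean())

    check_grads(f, [x, y], rtol=1e-3)


def test_concat_gradients(rng):
    a = tensor64(rng, 1, 2, 3, 3)
    b = tensor64(rng, 1, 4, 3, 3)
    check_grads(lambda: (concat([a, b], axis=1) ** 2).mean(), [a, b])


def test_broadcast_mul_gradients(rng):
    alpha = tensor64(rng, 1, 1, 4, 4)
    x = tensor64(rng, 1, 3, 4, 4)
    check_grads(lambda: (x * alpha.sigmoid()).mean(), [x, alpha])


def test_no_grad_builds_no_graph(rng):
    x = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    with no_grad():
        out = (x * 2.0).sum()
    assert not out.requires_grad


def test_seeded_init_is_deterministic():
    with seeded_init(99):
        c1 = Conv2d(3, 8, 3)
    with seeded_init(99):
        c2 = Conv2d(3, 8, 3)
    np.testing.assert_array_equal(c1.weight.data, c2.weight.data)


def test_adam_descends_quadratic():
    from manet.engine import Parameter

    p = Parameter(np.array([5.0, -3.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = (p * p).sum()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2
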