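"""Gradient and reduction-case checks for the autodiff core.

Every nontrivial primitive is checked against central finite differences on
tiny inputs; the convolution variants are additionally checked against
scipy-based oracles.
"""

import numpy as np
import pytest
from scipy import signal

from tsegan import nn

RNG = np.random.default_rng(0)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    flat, gflat = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g


def check_grads(build, tensors, tol=1e-6):
    """build() -> scalar Tensor using `tensors`; compare to finite diffs."""
    for t in tensors:
        t.zero_grad()
    out = build()
    out.backward()
    analytic = [t.grad.copy() for t in tensors]
    for t, ga in zip(tensors, analytic):
        gn = numeric_grad(lambda: build().data.item(), t.data)
        np.testing.assert_allclose(ga, gn, rtol=1e-4, atol=tol)


@pytest.mark.parametrize("op", [
    lambda x: (x * x + 2.0 * x).sum(),
    lambda x: (x.tanh() + x.sigmoid()).sum(),
    lambda x: x.relu().sum() + x.leaky_relu(0.2).mean(),
    lambda x: nn.softplus(x).sum(),
    lambda x: (x.abs() + (x * x + 0.5).log()).sum(),
    lambda x: x.mean(axis=(0, 1), keepdims=True).sum() + x.max(axis=1).sum(),
    lambda x: x.reshape(6, 4).transpose((1, 0)).sum(),
    lambda x: x[1:3, 2:5, :].sum(),
])
def test_elementwise_and_shape_grads(op):
    x = nn.Tensor(RNG.normal(size=(3, 4, 2)), requires_grad=True)
    check_grads(lambda: op(x), [x])


def test_matmul_and_broadcast_grads():
    a = nn.Tensor(RNG.normal(size=(3, 4)), requires_grad=True)
    b = nn.Tensor(RNG.normal(size=(4, 2)), requires_grad=True)
    c = nn.Tensor(RNG.normal(size=(2,)), requires_grad=True)
    check_grads(lambda: ((a @ b + c) ** 2.0).sum(), [a, b, c])


def test_concat_pad_grads():
    a = nn.Tensor(RNG.normal(size=(1, 2, 3, 3)), requires_grad=True)
    b = nn.Tensor(RNG.normal(size=(1, 3, 3, 3)), requires_grad=True)
    check_grads(lambda: (nn.concat([a, b], axis=1) ** 2.0).sum(), [a, b])
    check_grads(lambda: (nn.pad2d(a, (1, 2, 0, 1)) * 1.5).sum(), [a])
    check_grads(lambda: (nn.reflect_pad2d(a, 2) ** 2.0).sum(), [a])


def test_conv2d_matches_scipy():
    x = RNG.normal(size=(2, 3, 8, 8))
    w = RNG.normal(size=(4, 3, 3, 3))
    out = nn.conv2d(nn.Tensor(x), nn.Tensor(w), pad=1).data
    ref = np.zeros_like(out)
    for n in range(2):
        for o in range(4):
            acc = np.zeros((8, 8))
            for c in range(3):
                acc += signal.correlate2d(x[n, c], w[o, c], mode="same")
            ref[n, o] = acc
    np.testing.assert_allclose(out, ref, atol=1e-10)


@pytest.mark.parametrize("stride,pad", [(1, 1), (2, 1), (1, 0)])
def test_conv2d_grads(stride, pad):
    x = nn.Tensor(RNG.normal(size=(2, 2, 5, 5)), requires_grad=True)
    w = nn.Tensor(RNG.normal(size=(3, 2, 3, 3)), requires_grad=True)
    b = nn.Tensor(RNG.normal(size=(3,)), requires_grad=True)
    check_grads(lambda: (nn.conv2d(x, w, b, stride=stride, pad=pad) ** 2.0).sum(),
                [x, w, b])


def test_conv_transpose_doubles_and_grads():
    x = nn.Tensor(RNG.normal(size=(1, 2, 4, 4)), requires_grad=True)
    w = nn.Tensor(RNG.normal(size=(2, 3, 4, 4)), requires_grad=True)
    out = nn.conv_transpose2d(x, w, stride=2, pad=1)
    assert out.shape == (1, 3, 8, 8)
    check_grads(lambda: (nn.conv_transpose2d(x, w, stride=2, pad=1) ** 2.0).sum(),
                [x, w])


def test_conv_transpose_adjoint_of_conv():
    """<conv(x), y> == <x, conv_transpose(y)> with shared kernel."""
    x = RNG.normal(size=(1, 2, 8, 8))
    y = RNG.normal(size=(1, 3, 4, 4))
    w = RNG.normal(size=(3, 2, 4, 4))
    cx = nn.conv2d(nn.Tensor(x), nn.Tensor(w), stride=2, pad=1).data
    # transposed conv uses (Cin,Cout) kernel layout
    ty = nn.conv_transpose2d(nn.Tensor(y), nn.Tensor(w.transpose(0, 1, 2, 3)),
                             stride=2, pad=1).data
    assert ty.shape == x.shape
    np.testing.assert_allclose((cx * y).sum(), (x * ty).sum(), rtol=1e-10)


def test_depthwise_blur_grads():
    k = RNG.uniform(size=(3, 3))
    k /= k.sum()
    x = nn.Tensor(RNG.normal(size=(1, 2, 5, 5)), requires_grad=True)
    check_grads(lambda: (nn.depthwise_conv2d(x, k) ** 2.0).sum(), [x])


class TestDeformConv:
    def test_zero_offsets_reduce_to_conv(self):
        x = nn.Tensor(RNG.normal(size=(2, 4, 16, 16)))
        w = nn.Tensor(RNG.normal(size=(3, 4, 3, 3)))
        off = nn.Tensor(np.zeros((2, 18, 16, 16)))
        out = nn.deform_conv2d(x, off, w, pad=1).data
        ref = nn.conv2d(x, w, pad=1).data
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_integer_shift_equals_shifted_conv_interior(self):
        """Offset (0,1) everywhere samples the column-shifted input."""
        x = RNG.normal(size=(1, 2, 10, 10))
        w = nn.Tensor(RNG.normal(size=(2, 2, 3, 3)))
        off = np.zeros((1, 18, 10, 10))
        off[:, 1::2] = 1.0  # dx = +1 for every tap
        out = nn.deform_conv2d(nn.Tensor(x), nn.Tensor(off), w, pad=1).data
        xs = np.roll(x, -1, axis=3)  # column-shifted input
        ref = nn.conv2d(nn.Tensor(xs), w, pad=1).data
        np.testing.assert_allclose(out[:, :, 2:-2, 2:-2], ref[:, :, 2:-2, 2:-2],
                                   atol=1e-8)

    def test_constant_input_any_offsets(self):
        """Interior output of a constant image is offset-invariant."""
        x = np.full((1, 1, 12, 12), 3.0)
        w = nn.Tensor(RNG.normal(size=(1, 1, 3, 3)))
        off = nn.Tensor(RNG.uniform(-1.5, 1.5, size=(1, 18, 12, 12)))
        out = nn.deform_conv2d(nn.Tensor(x), off, w, pad=1).data
        expected = 3.0 * w.data.sum()
        np.testing.assert_allclose(out[:, :, 3:-3, 3:-3], expected, atol=1e-8)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_grads(self, stride):
        H = 6
        Ho = (H + 2 - 3) // stride + 1
        x = nn.Tensor(RNG.normal(size=(1, 2, H, H)), requires_grad=True)
        w = nn.Tensor(RNG.normal(size=(2, 2, 3, 3)), requires_grad=True)
        b = nn.Tensor(RNG.normal(size=(2,)), requires_grad=True)
        off = nn.Tensor(RNG.uniform(-0.4, 0.4, size=(1, 18, Ho, Ho)),
                        requires_grad=True)
        check_grads(
            lambda: (nn.deform_conv2d(x, off, w, b, stride=stride, pad=1)
                     ** 2.0).sum(),
            [x, w, b, off], tol=1e-5)


def test_batchnorm_normalizes_and_has_grads():
    rng = np.random.default_rng(3)
    bn = nn.BatchNorm2d(3)
    x = nn.Tensor(rng.normal(2.0, 3.0, size=(4, 3, 5, 5)), requires_grad=True)
    y = bn(x)
    np.testing.assert_allclose(y.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
    np.testing.assert_allclose(y.data.var(axis=(0, 2, 3)), 1.0, atol=1e-3)
    y.sum().backward()
    assert bn.gamma.grad is not None and np.isfinite(x.grad).all()


def test_adam_minimizes_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = (p * p).sum()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_module_state_dict_roundtrip():
    rng = np.random.default_rng(1)
    m = nn.Sequential(nn.Conv2d(2, 4, 3, rng), nn.BatchNorm2d(4),
                      nn.Conv2d(4, 1, 3, rng))
    state = m.state_dict()
    rng2 = np.random.default_rng(9)
    m2 = nn.Sequential(nn.Conv2d(2, 4, 3, rng2), nn.BatchNorm2d(4),
                       nn.Conv2d(4, 1, 3, rng2))
    m2.load_state_dict(state)
    x = nn.Tensor(np.random.default_rng(2).normal(size=(1, 2, 8, 8)))
    np.testing.assert_array_equal(m.eval()(x).data, m2.eval()(x).data)
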