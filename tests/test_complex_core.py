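"""Complex layer algebra: oracle equivalence, gradients, parameter counts."""

import numpy as np
import pytest

from cvfair import complex_core as cc
from cvfair.complex_core import (
    ComplexTensor,
    complex_avg_pool,
    complex_conv2d,
    complex_linear,
    complex_relu,
    count_parameters,
    magnitude_readout,
)
from cvfair.exceptions import GeometryError


def random_ct(rng, shape):
    return ComplexTensor(rng.normal(size=shape), rng.normal(size=shape))


def brute_force_conv(x: np.ndarray, w: np.ndarray, stride=1):
    """Native-complex sliding-window cross-correlation (independent oracle)."""
    n, ci, h, wd = x.shape
    o, _, kh, kw = w.shape
    oh = (h - kh) // stride + 1
    ow = (wd - kw) // stride + 1
    out = np.zeros((n, o, oh, ow), dtype=complex)
    for b in range(n):
        for oc in range(o):
            for i in range(oh):
                for j in range(ow):
                    patch = x[b, :, i * stride : i * stride + kh,
                              j * stride : j * stride + kw]
                    out[b, oc, i, j] = np.sum(patch * w[oc])
    return out


class TestComplexConv2d:
    def test_identity_kernel(self, rng):
        x = random_ct(rng, (1, 1, 4, 4))
        w = ComplexTensor(np.ones((1, 1, 1, 1)), np.zeros((1, 1, 1, 1)))
        out = complex_conv2d(x, w)
        assert np.allclose(out.real, x.real) and np.allclose(out.imag, x.imag)

    def test_imaginary_unit_kernel(self, rng):
        x = ComplexTensor(rng.normal(size=(1, 1, 3, 3)), np.zeros((1, 1, 3, 3)))
        w = ComplexTensor(np.zeros((1, 1, 1, 1)), np.ones((1, 1, 1, 1)))
        out = complex_conv2d(x, w)
        assert np.allclose(out.real, 0.0)
        assert np.allclose(out.imag, x.real)

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = random_ct(rng, (1, 1, 4, 4))
        w = random_ct(rng, (1, 1, 2, 2))
        out = complex_conv2d(x, w).to_complex()
        expected = brute_force_conv(x.to_complex(), w.to_complex())
        assert np.max(np.abs(out - expected)) < 1e-10

    def test_linearity_in_input(self, rng):
        x, y = random_ct(rng, (1, 2, 5, 5)), random_ct(rng, (1, 2, 5, 5))
        w = random_ct(rng, (3, 2, 3, 3))
        alpha = 1.7
        lhs = complex_conv2d(
            ComplexTensor(alpha * x.real + y.real, alpha * x.imag + y.imag), w
        )
        a = complex_conv2d(x, w)
        b = complex_conv2d(y, w)
        assert np.allclose(lhs.real, alpha * a.real + b.real, atol=1e-10)
        assert np.allclose(lhs.imag, alpha * a.imag + b.imag, atol=1e-10)

    def test_real_embedding_reduces_to_real_conv(self, rng):
        """With all imaginary parts zero the complex convolution IS the
        real convolution (the zero-imaginary special case)."""
        xr = rng.normal(size=(2, 3, 6, 6))
        wr = rng.normal(size=(4, 3, 3, 3))
        out = complex_conv2d(ComplexTensor(xr, np.zeros_like(xr)),
                             ComplexTensor(wr, np.zeros_like(wr)))
        assert np.allclose(out.imag, 0.0)
        expected = brute_force_conv(xr.astype(complex), wr.astype(complex)).real
        assert np.allclose(out.real, expected, atol=1e-10)

    def test_kernel_too_large(self, rng):
        with pytest.raises(GeometryError):
            complex_conv2d(random_ct(rng, (1, 1, 2, 2)), random_ct(rng, (1, 1, 4, 4)))

    def test_flip_kernel_is_true_convolution(self, rng):
        x = random_ct(rng, (1, 1, 4, 4))
        w = random_ct(rng, (1, 1, 2, 2))
        flipped = ComplexTensor(w.real[:, :, ::-1, ::-1], w.imag[:, :, ::-1, ::-1])
        a = complex_conv2d(x, w, flip_kernel=True).to_complex()
        b = complex_conv2d(x, flipped).to_complex()
        assert np.allclose(a, b, atol=1e-12)


class TestComplexRelu:
    def test_pass_through(self):
        z = ComplexTensor(np.array([3.0]), np.array([2.0]))
        out = complex_relu(z)
        assert out.real[0] == 3.0 and out.imag[0] == 2.0

    def test_blocked_negative_real(self):
        out = complex_relu(ComplexTensor(np.array([-1.0]), np.array([2.0])))
        assert out.real[0] == 0.0 and out.imag[0] == 0.0

    def test_boundary_strict(self):
        out = complex_relu(ComplexTensor(np.array([3.0]), np.array([0.0])))
        assert out.real[0] == 0.0 and out.imag[0] == 0.0

    def test_idempotent_and_signs(self, rng):
        z = random_ct(rng, (50,))
        once = complex_relu(z)
        twice = complex_relu(once)
        assert np.array_equal(once.real, twice.real)
        assert np.array_equal(once.imag, twice.imag)
        passed = (once.real > 0) & (once.imag > 0)
        blocked = ~passed
        assert np.all(once.real[blocked] == 0) and np.all(once.imag[blocked] == 0)
        assert np.all(once.real[passed] > 0) and np.all(once.imag[passed] > 0)


class TestComplexAvgPool:
    def test_constant_field(self):
        z = ComplexTensor(np.full((1, 1, 4, 4), 2.5), np.full((1, 1, 4, 4), -1.5))
        out = complex_avg_pool(z, 2)
        assert np.allclose(out.real, 2.5) and np.allclose(out.imag, -1.5)

    def test_two_value_window(self):
        z = ComplexTensor(np.array([[[[1.0, 3.0], [1.0, 3.0]]]]),
                          np.array([[[[1.0, 3.0], [1.0, 3.0]]]]))
        out = complex_avg_pool(z, 2)
        assert out.real[0, 0, 0, 0] == 2.0 and out.imag[0, 0, 0, 0] == 2.0

    def test_matches_real_pooling_oracle(self, rng):
        xr = rng.normal(size=(1, 2, 6, 6))
        out = complex_avg_pool(ComplexTensor(xr, np.zeros_like(xr)), 2)
        # independent oracle: mean over 2x2 blocks via reshape
        expected = xr.reshape(1, 2, 3, 2, 3, 2).mean(axis=(3, 5))
        assert np.allclose(out.real, expected, atol=1e-12)
        assert np.allclose(out.imag, 0.0)

    def test_window_too_large(self, rng):
        with pytest.raises(GeometryError):
            complex_avg_pool(random_ct(rng, (1, 1, 2, 2)), 4)


class TestComplexLinear:
    def test_identity(self, rng):
        x = random_ct(rng, (3,))
        W = ComplexTensor(np.eye(3), np.zeros((3, 3)))
        y = complex_linear(x, W)
        assert np.allclose(y.to_complex(), x.to_complex())

    def test_imaginary_unit_weight(self):
        x = ComplexTensor(np.array([1.0]), np.array([1.0]))
        W = ComplexTensor(np.array([[0.0]]), np.array([[1.0]]))
        y = complex_linear(x, W)
        assert np.isclose(y.real[0], -1.0) and np.isclose(y.imag[0], 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_native_complex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, W = random_ct(rng, (3,)), random_ct(rng, (2, 3))
        b = random_ct(rng, (2,))
        y = complex_linear(x, W, b).to_complex()
        expected = W.to_complex() @ x.to_complex() + b.to_complex()
        assert np.max(np.abs(y - expected)) < 1e-12

    def test_conjugating_variant(self, rng):
        x, W = random_ct(rng, (3,)), random_ct(rng, (2, 3))
        y = complex_linear(x, W, conjugate_weights=True).to_complex()
        expected = np.conj(W.to_complex()) @ x.to_complex()
        assert np.max(np.abs(y - expected)) < 1e-12


class TestMagnitudeReadout:
    def test_three_four_five(self):
        assert magnitude_readout(ComplexTensor(np.array([3.0]), np.array([4.0])))[0] == 5.0

    def test_zero(self):
        assert magnitude_readout(ComplexTensor(np.array([0.0]), np.array([0.0])))[0] == 0.0

    def test_vector(self):
        out = magnitude_readout(ComplexTensor(np.array([1.0, 2.0]), np.array([1.0, 0.0])))
        assert np.allclose(out, [np.sqrt(2.0), 2.0])


class TestCountParameters:
    def test_complex_conv_counts(self):
        layer = cc.ComplexConv2d(2, 4, 3, bias=True)
        assert count_parameters(layer, "complex") == 3 * 3 * 2 * 4 + 4  # 76
        assert count_parameters(layer, "real_scalar") == 152

    def test_parameter_free_layers(self):
        assert count_parameters(cc.ComplexAvgPool2d(2)) == 0
        assert count_parameters(cc.ComplexReLU()) == 0

    def test_real_dense_counts(self):
        layer = cc.RealLinear(10, 5, bias=True)
        assert count_parameters(layer, "real_scalar") == 55
        with pytest.raises(ValueError):
            count_parameters(layer, "complex")


# -- gradient checks ---------------------------------------------------------


def finite_difference_check(layer, x, seed=0, h=1e-6, n_checks=6):
    """Compare analytic parameter gradients of sum(out^2)/2 against central
    differences. Works for both complex and real layers."""
    rng = np.random.default_rng(seed)

    def loss():
        out = layer.forward(x)
        if isinstance(out, ComplexTensor):
            return 0.5 * float(np.sum(out.real**2) + np.sum(out.imag**2))
        return 0.5 * float(np.sum(out**2))

    def run_backward():
        out = layer.forward(x)
        for p in layer.parameters():
            p.zero_grad()
        if isinstance(out, ComplexTensor):
            layer.backward(ComplexTensor(out.real, out.imag))
        else:
            layer.backward(out)

    run_backward()
    worst = 0.0
    for p in layer.parameters():
        for comp in ("real", "imag"):
            arr = getattr(p, comp)
            if arr is None:
                continue
            grad = getattr(p, f"grad_{comp}")
            flat_idx = rng.choice(arr.size, size=min(n_checks, arr.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss()
                arr[idx] = orig - h
                lm = loss()
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = grad[idx]
                denom = max(1e-6, abs(fd) + abs(an))
                worst = max(worst, abs(fd - an) / denom)
    return worst


@pytest.mark.parametrize(
    "layer_factory,shape,is_complex",
    [
        (lambda r: cc.ComplexConv2d(2, 3, 3, padding=1, rng=r), (2, 2, 5, 5), True),
        (lambda r: cc.ComplexLinear(6, 4, rng=r), (3, 6), True),
        (lambda r: cc.RealConv2d(2, 3, 3, padding=1, rng=r), (2, 2, 5, 5), False),
        (lambda r: cc.RealLinear(6, 4, rng=r), (3, 6), False),
    ],
    ids=["cconv", "cdense", "rconv", "rdense"],
)
def test_layer_gradients_match_finite_differences(layer_factory, shape, is_complex):
    rng = np.random.default_rng(42)
    layer = layer_factory(rng)
    x = (ComplexTensor(rng.normal(size=shape), rng.normal(size=shape))
         if is_complex else rng.normal(size=shape))
    assert finite_difference_check(layer, x) < 1e-4
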