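"""Complex-valued layer algebra over paired real arrays.

A complex activation or weight tensor is carried as a pair of equal-shape
real arrays (real part, imaginary part), so that ordinary real-valued
backpropagation trains the network: the two components of each complex
weight are learned jointly as an "even real-valued tensor".

The operations here are the building blocks of a complex-valued CNN:

* :func:`complex_conv2d` — convolution with the standard complex product
  ``(a+bi)(c+di) = (ac-bd) + (ad+bc)i`` accumulated over the kernel support;
* :func:`complex_relu` — the zReLU gate: a value passes unchanged only when
  both its real and imaginary parts are strictly positive;
* :func:`complex_avg_pool` — arithmetic mean per window, applied to each
  component (equal to the complex mean by linearity);
* :func:`complex_linear` — the bilinear (non-conjugating) complex
  matrix-vector product;
* :func:`magnitude_readout` — modulus projection to real class scores.

Layer classes with explicit ``forward``/``backward`` passes (used by the
``architectures`` and ``training_eval`` modules) live alongside the
functional API. Convolution follows the deep-learning cross-correlation
convention; set ``flip_kernel=True`` for true convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "ComplexTensor",
    "Parameter",
    "complex_conv2d",
    "complex_relu",
    "complex_avg_pool",
    "complex_linear",
    "magnitude_readout",
    "count_parameters",
    "ComplexConv2d",
    "ComplexLinear",
    "ComplexReLU",
    "ComplexAvgPool2d",
    "ComplexFlatten",
    "MagnitudeReadout",
    "RealPartReadout",
    "RealConv2d",
    "RealLinear",
    "RealReLU",
    "RealAvgPool2d",
    "RealFlatten",
    "ScoreReadout",
]


@dataclass
class ComplexTensor:
    """A complex array carried as paired real arrays of identical shape."""

    real: np.ndarray
    imag: np.ndarray

    def __post_init__(self) -> None:
        self.real = np.asarray(self.real, dtype=float)
        self.imag = np.asarray(self.imag, dtype=float)
        if self.real.shape != self.imag.shape:
            raise GeometryError(
                f"component shapes differ: {self.real.shape} vs {self.imag.shape}"
            )

    @classmethod
    def from_complex(cls, z: np.ndarray) -> "ComplexTensor":
        z = np.asarray(z)
        return cls(np.ascontiguousarray(z.real), np.ascontiguousarray(z.imag))

    @classmethod
    def zeros(cls, shape) -> "ComplexTensor":
        return cls(np.zeros(shape), np.zeros(shape))

    def to_complex(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @property
    def shape(self):
        return self.real.shape

    def copy(self) -> "ComplexTensor":
        return ComplexTensor(self.real.copy(), self.imag.copy())


class Parameter:
    """A trainable tensor; complex parameters hold both components.

    The optimizer treats a complex parameter as one unit: first moments are
    kept per component while the second-moment accumulator is shared and
    driven by the squared gradient modulus.
    """

    def __init__(self, real: np.ndarray, imag: np.ndarray | None = None, name: str = ""):
        self.real = np.asarray(real, dtype=float)
        self.imag = None if imag is None else np.asarray(imag, dtype=float)
        if self.imag is not None and self.imag.shape != self.real.shape:
            raise GeometryError("parameter component shapes differ")
        self.name = name
        self.grad_real = np.zeros_like(self.real)
        self.grad_imag = None if self.imag is None else np.zeros_like(self.imag)

    @property
    def is_complex(self) -> bool:
        return self.imag is not None

    def zero_grad(self) -> None:
        self.grad_real[...] = 0.0
        if self.grad_imag is not None:
            self.grad_imag[...] = 0.0

    @property
    def size(self) -> int:
        return self.real.size


# ---------------------------------------------------------------------------
# im2col machinery shared by real and complex convolutions
# ---------------------------------------------------------------------------


def _out_hw(h: int, w: int, kh: int, kw: int, stride: int, padding: int):
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    if oh < 1 or ow < 1:
        raise GeometryError(
            f"kernel {kh}x{kw} with stride {stride}, padding {padding} "
            f"does not fit input {h}x{w}"
        )
    return oh, ow


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, oh*ow) patch matrix."""
    n, c, h, w = x.shape
    oh, ow = _out_hw(h, w, kh, kw, stride, padding)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    s0, s1, s2, s3 = x.strides
    shape = (n, c, kh, kw, oh, ow)
    strides = (s0, s1, s2, s3, stride * s2, stride * s3)
    patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return patches.reshape(n, c * kh * kw, oh * ow).copy(), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, padding: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    oh, ow = _out_hw(h, w, kh, kw, stride, padding)
    hp, wp = h + 2 * padding, w + 2 * padding
    out = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------


def _real_conv2d(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    """Real-valued cross-correlation of (N,C,H,W) with (O,C,kh,kw)."""
    n, c, h, wd = x.shape
    o, cw, kh, kw = w.shape
    if c != cw:
        raise GeometryError(f"input channels {c} != kernel channels {cw}")
    cols, oh, ow = _im2col(x, kh, kw, stride, padding)
    out = np.einsum("ok,nkl->nol", w.reshape(o, -1), cols)
    return out.reshape(n, o, oh, ow)


def complex_conv2d(
    x: ComplexTensor,
    w: ComplexTensor,
    stride: int = 1,
    padding: int = 0,
    flip_kernel: bool = False,
) -> ComplexTensor:
    """Complex 2-D convolution of ``x`` (N,C,H,W) with kernels ``w`` (O,C,kh,kw).

    The complex product is accumulated over the kernel support:
    ``out = conv(xr, wr) - conv(xi, wi) + i*(conv(xr, wi) + conv(xi, wr))``,
    identical to forming native complex numbers and multiply-summing them.
    Cross-correlation orientation by default; ``flip_kernel=True`` gives the
    flipped-kernel (true convolution) orientation.
    """
    wr, wi = w.real, w.imag
    if flip_kernel:
        wr, wi = wr[:, :, ::-1, ::-1], wi[:, :, ::-1, ::-1]
    rr = _real_conv2d(x.real, wr, stride, padding)
    ii = _real_conv2d(x.imag, wi, stride, padding)
    ri = _real_conv2d(x.real, wi, stride, padding)
    ir = _real_conv2d(x.imag, wr, stride, padding)
    return ComplexTensor(rr - ii, ri + ir)


def complex_relu(z: ComplexTensor) -> ComplexTensor:
    """zReLU: pass z only where real > 0 AND imag > 0 (strict), else 0."""
    mask = (z.real > 0) & (z.imag > 0)
    return ComplexTensor(np.where(mask, z.real, 0.0), np.where(mask, z.imag, 0.0))


def complex_avg_pool(z: ComplexTensor, window: int, stride: int | None = None) -> ComplexTensor:
    """Average pooling per window, applied to each component independently.

    By linearity of the mean this equals the complex arithmetic mean of each
    window. Input layout (..., H, W); windows that do not fit are dropped
    (floor behaviour).
    """
    stride = window if stride is None else stride
    return ComplexTensor(
        _avg_pool_real(z.real, window, stride), _avg_pool_real(z.imag, window, stride)
    )


def _avg_pool_real(x: np.ndarray, window: int, stride: int) -> np.ndarray:
    h, w = x.shape[-2:]
    if window > h or window > w:
        raise GeometryError(f"pool window {window} larger than input {h}x{w}")
    oh = (h - window) // stride + 1
    ow = (w - window) // stride + 1
    out = np.zeros(x.shape[:-2] + (oh, ow))
    for i in range(window):
        for j in range(window):
            out += x[..., i : i + stride * oh : stride, j : j + stride * ow : stride]
    return out / (window * window)


def complex_linear(
    x: ComplexTensor, W: ComplexTensor, b: ComplexTensor | None = None,
    conjugate_weights: bool = False,
) -> ComplexTensor:
    """Bilinear complex affine map ``y = W x + b``.

    ``x`` is a vector (d,) or batch (N, d); ``W`` is (out, d). The product is
    the non-conjugating complex multiply-accumulate; ``conjugate_weights=True``
    switches to the conjugating (Hermitian inner product) variant.
    """
    wr, wi = W.real, (-W.imag if conjugate_weights else W.imag)
    if x.real.ndim == 1:
        yr = x.real @ wr.T - x.imag @ wi.T
        yi = x.real @ wi.T + x.imag @ wr.T
    else:
        yr = x.real @ wr.T - x.imag @ wi.T
        yi = x.real @ wi.T + x.imag @ wr.T
    if b is not None:
        yr = yr + b.real
        yi = yi + b.imag
    return ComplexTensor(yr, yi)


def magnitude_readout(z: ComplexTensor) -> np.ndarray:
    """Elementwise modulus sqrt(real^2 + imag^2) -> real array."""
    return np.hypot(z.real, z.imag)


def count_parameters(layer, unit: str = "complex") -> int:
    """Count trainable parameters of a layer description or layer module.

    For a complex conv/dense layer the count in complex units is
    ``kh*kw*in*out (+ out if bias)``; one complex unit is two real scalars.
    Real layers count scalars directly (and have no complex-unit reading).
    Pooling/activation/flatten/readout layers are parameter-free.
    """
    if unit not in ("complex", "real_scalar"):
        raise ValueError(f"unknown unit {unit!r}")
    kind = getattr(layer, "kind", None)
    if kind is None:
        from .exceptions import ConfigurationError

        raise ConfigurationError(f"object {layer!r} does not describe a layer")
    if kind in ("pool", "act", "activation", "flatten", "readout"):
        return 0
    domain = getattr(layer, "domain", "complex")
    if kind == "conv":
        k = layer.kernel
        units = k * k * layer.in_channels * layer.out_channels
        if layer.bias:
            units += layer.out_channels
    elif kind == "dense":
        units = layer.in_features * layer.out_features
        if layer.bias:
            units += layer.out_features
    else:
        raise ValueError(f"unknown layer kind {kind!r}")
    if domain == "complex":
        return units if unit == "complex" else 2 * units
    if unit == "complex":
        raise ValueError("real layers have no complex-unit parameter count")
    return units


# ---------------------------------------------------------------------------
# Layer modules with explicit backward passes
# ---------------------------------------------------------------------------


def _init_pair(rng: np.random.Generator, shape, fan_in: int):
    """Variance-scaled init; each component gets half the target variance."""
    sigma = np.sqrt(1.0 / fan_in)
    return (
        rng.normal(0.0, sigma / np.sqrt(2.0), size=shape),
        rng.normal(0.0, sigma / np.sqrt(2.0), size=shape),
    )


class _Module:
    kind = "abstract"

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class ComplexConv2d(_Module):
    """Complex convolution layer (cross-correlation orientation)."""

    kind = "conv"
    domain = "complex"

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 bias=True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.bias = bias
        fan_in = in_channels * kernel * kernel
        wr, wi = _init_pair(rng, (out_channels, in_channels, kernel, kernel), fan_in)
        self.weight = Parameter(wr, wi, name="conv.weight")
        self.b = Parameter(np.zeros(out_channels), np.zeros(out_channels),
                           name="conv.bias") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.b] if self.b is not None else [])

    def forward(self, x: ComplexTensor) -> ComplexTensor:
        k, s, p = self.kernel, self.stride, self.padding
        cols_r, oh, ow = _im2col(x.real, k, k, s, p)
        cols_i, _, _ = _im2col(x.imag, k, k, s, p)
        wr = self.weight.real.reshape(self.out_channels, -1)
        wi = self.weight.imag.reshape(self.out_channels, -1)
        yr = np.einsum("ok,nkl->nol", wr, cols_r) - np.einsum("ok,nkl->nol", wi, cols_i)
        yi = np.einsum("ok,nkl->nol", wi, cols_r) + np.einsum("ok,nkl->nol", wr, cols_i)
        n = x.real.shape[0]
        yr = yr.reshape(n, self.out_channels, oh, ow)
        yi = yi.reshape(n, self.out_channels, oh, ow)
        if self.b is not None:
            yr = yr + self.b.real[None, :, None, None]
            yi = yi + self.b.imag[None, :, None, None]
        self._cache = (cols_r, cols_i, x.real.shape, (oh, ow))
        return ComplexTensor(yr, yi)

    def backward(self, grad: ComplexTensor) -> ComplexTensor:
        cols_r, cols_i, x_shape, (oh, ow) = self._cache
        n = x_shape[0]
        k, s, p = self.kernel, self.stride, self.padding
        gr = grad.real.reshape(n, self.out_channels, oh * ow)
        gi = grad.imag.reshape(n, self.out_channels, oh * ow)
        wr = self.weight.real.reshape(self.out_channels, -1)
        wi = self.weight.imag.reshape(self.out_channels, -1)
        # d/dW of yr = Wr*cr - Wi*ci ; yi = Wi*cr + Wr*ci
        gwr = np.einsum("nol,nkl->ok", gr, cols_r) + np.einsum("nol,nkl->ok", gi, cols_i)
        gwi = -np.einsum("nol,nkl->ok", gr, cols_i) + np.einsum("nol,nkl->ok", gi, cols_r)
        self.weight.grad_real += gwr.reshape(self.weight.real.shape)
        self.weight.grad_imag += gwi.reshape(self.weight.imag.shape)
        if self.b is not None:
            self.b.grad_real += gr.sum(axis=(0, 2))
            self.b.grad_imag += gi.sum(axis=(0, 2))
        gcols_r = np.einsum("ok,nol->nkl", wr, gr) + np.einsum("ok,nol->nkl", wi, gi)
        gcols_i = -np.einsum("ok,nol->nkl", wi, gr) + np.einsum("ok,nol->nkl", wr, gi)
        gx_r = _col2im(gcols_r, x_shape, k, k, s, p)
        gx_i = _col2im(gcols_i, x_shape, k, k, s, p)
        return ComplexTensor(gx_r, gx_i)


class ComplexLinear(_Module):
    kind = "dense"
    domain = "complex"

    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.bias = bias
        wr, wi = _init_pair(rng, (out_features, in_features), in_features)
        self.weight = Parameter(wr, wi, name="dense.weight")
        self.b = Parameter(np.zeros(out_features), np.zeros(out_features),
                           name="dense.bias") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.b] if self.b is not None else [])

    def forward(self, x: ComplexTensor) -> ComplexTensor:
        self._cache = x
        y = complex_linear(x, ComplexTensor(self.weight.real, self.weight.imag))
        if self.b is not None:
            y = ComplexTensor(y.real + self.b.real, y.imag + self.b.imag)
        return y

    def backward(self, grad: ComplexTensor) -> ComplexTensor:
        x = self._cache
        wr, wi = self.weight.real, self.weight.imag
        self.weight.grad_real += grad.real.T @ x.real + grad.imag.T @ x.imag
        self.weight.grad_imag += -grad.real.T @ x.imag + grad.imag.T @ x.real
        if self.b is not None:
            self.b.grad_real += grad.real.sum(axis=0)
            self.b.grad_imag += grad.imag.sum(axis=0)
        gx_r = grad.real @ wr + grad.imag @ wi
        gx_i = -grad.real @ wi + grad.imag @ wr
        return ComplexTensor(gx_r, gx_i)


class ComplexReLU(_Module):
    """Complex activation gate.

    ``mode="zrelu"`` (default): pass z unchanged only when both components
    are strictly positive, else 0 (the study's activation). ``mode="split"``
    applies ReLU to each component independently; unlike zReLU it restricts
    to the ordinary ReLU on the real line, which makes the real network an
    exact zero-imaginary special case of the complex one.
    """

    kind = "act"
    domain = "complex"

    def __init__(self, mode: str = "zrelu"):
        if mode not in ("zrelu", "split"):
            raise ValueError(f"unknown activation mode {mode!r}")
        self.mode = mode
        self._mask = None

    def forward(self, z: ComplexTensor) -> ComplexTensor:
        if self.mode == "zrelu":
            mask = (z.real > 0) & (z.imag > 0)
            self._mask = (mask, mask)
        else:
            self._mask = (z.real > 0, z.imag > 0)
        mr, mi = self._mask
        return ComplexTensor(np.where(mr, z.real, 0.0), np.where(mi, z.imag, 0.0))

    def backward(self, grad: ComplexTensor) -> ComplexTensor:
        # subgradient 0 on the blocked set
        mr, mi = self._mask
        return ComplexTensor(np.where(mr, grad.real, 0.0),
                             np.where(mi, grad.imag, 0.0))


class ComplexAvgPool2d(_Module):
    kind = "pool"
    domain = "complex"

    def __init__(self, window: int, stride: int | None = None):
        self.window = window
        self.stride = window if stride is None else stride
        self._in_shape = None

    def forward(self, z: ComplexTensor) -> ComplexTensor:
        self._in_shape = z.shape
        return complex_avg_pool(z, self.window, self.stride)

    def backward(self, grad: ComplexTensor) -> ComplexTensor:
        return ComplexTensor(
            _avg_pool_backward(grad.real, self._in_shape, self.window, self.stride),
            _avg_pool_backward(grad.imag, self._in_shape, self.window, self.stride),
        )


def _avg_pool_backward(g: np.ndarray, in_shape, window: int, stride: int) -> np.ndarray:
    out = np.zeros(in_shape)
    oh, ow = g.shape[-2:]
    gw = g / (window * window)
    for i in range(window):
        for j in range(window):
            out[..., i : i + stride * oh : stride, j : j + stride * ow : stride] += gw
    return out


class ComplexFlatten(_Module):
    kind = "flatten"
    domain = "complex"

    def __init__(self):
        self._shape = None

    def forward(self, z: ComplexTensor) -> ComplexTensor:
        self._shape = z.shape
        n = z.shape[0]
        return ComplexTensor(z.real.reshape(n, -1), z.imag.reshape(n, -1))

    def backward(self, grad: ComplexTensor) -> ComplexTensor:
        return ComplexTensor(grad.real.reshape(self._shape), grad.imag.reshape(self._shape))


class MagnitudeReadout(_Module):
    """Projects complex class scores to real ones via the modulus."""

    kind = "readout"
    domain = "complex"
    _EPS = 1e-12

    def __init__(self):
        self._cache = None

    def forward(self, z: ComplexTensor) -> np.ndarray:
        mag = np.hypot(z.real, z.imag)
        self._cache = (z, mag)
        return mag

    def backward(self, grad: np.ndarray) -> ComplexTensor:
        z, mag = self._cache
        denom = np.maximum(mag, self._EPS)
        return ComplexTensor(grad * z.real / denom, grad * z.imag / denom)


class RealPartReadout(_Module):
    """Projects complex class scores to their real parts (configuration
    alternative to the magnitude readout; the exact inverse embedding of a
    real network's scores)."""

    kind = "readout"
    domain = "complex"

    def forward(self, z: ComplexTensor) -> np.ndarray:
        return z.real

    def backward(self, grad: np.ndarray) -> ComplexTensor:
        return ComplexTensor(grad, np.zeros_like(grad))


# -- real-valued counterparts ------------------------------------------------


class RealConv2d(_Module):
    kind = "conv"
    domain = "real"

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 bias=True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.bias = bias
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel, kernel)),
            name="conv.weight",
        )
        self.b = Parameter(np.zeros(out_channels), name="conv.bias") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        cols, oh, ow = _im2col(x, k, k, s, p)
        w2 = self.weight.real.reshape(self.out_channels, -1)
        y = np.einsum("ok,nkl->nol", w2, cols).reshape(x.shape[0], self.out_channels, oh, ow)
        if self.b is not None:
            y = y + self.b.real[None, :, None, None]
        self._cache = (cols, x.shape, (oh, ow))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (oh, ow) = self._cache
        n = x_shape[0]
        k, s, p = self.kernel, self.stride, self.padding
        g = grad.reshape(n, self.out_channels, oh * ow)
        w2 = self.weight.real.reshape(self.out_channels, -1)
        self.weight.grad_real += np.einsum("nol,nkl->ok", g, cols).reshape(
            self.weight.real.shape
        )
        if self.b is not None:
            self.b.grad_real += g.sum(axis=(0, 2))
        gcols = np.einsum("ok,nol->nkl", w2, g)
        return _col2im(gcols, x_shape, k, k, s, p)


class RealLinear(_Module):
    kind = "dense"
    domain = "real"

    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.bias = bias
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features)),
            name="dense.weight",
        )
        self.b = Parameter(np.zeros(out_features), name="dense.bias") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        y = x @ self.weight.real.T
        if self.b is not None:
            y = y + self.b.real
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad_real += grad.T @ x
        if self.b is not None:
            self.b.grad_real += grad.sum(axis=0)
        return grad @ self.weight.real


class RealReLU(_Module):
    kind = "act"
    domain = "real"

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class RealAvgPool2d(_Module):
    kind = "pool"
    domain = "real"

    def __init__(self, window: int, stride: int | None = None):
        self.window = window
        self.stride = window if stride is None else stride
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return _avg_pool_real(x, self.window, self.stride)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return _avg_pool_backward(grad, self._in_shape, self.window, self.stride)


class RealFlatten(_Module):
    kind = "flatten"
    domain = "real"

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class ScoreReadout(_Module):
    """Identity readout for real networks (scores are already real)."""

    kind = "readout"
    domain = "real"

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad
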