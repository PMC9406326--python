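"""Image preprocessing and real-to-complex domain conversion.

Real images are standardized (per-image zero mean, unit standard deviation)
and optionally resized, then converted into the complex domain by a discrete
Fourier transform expressed as multiplication with the Fourier/Vandermonde
matrix ``F[j, k] = w_N^(j*k)``, ``w_N = exp(-2*pi*i/N)``. Because the input
is real, the spectrum is Hermitian-symmetric (``X[k] = conj(X[N-k])``) and
only the first ``floor(W/2) + 1`` coefficients carry independent
information; the conversion keeps exactly that non-redundant half, reducing
the component count to "almost half" of the original width.

By default the transform runs along the width axis of each row and channel,
preserving the spatial layout that the convolutional layers exploit;
``axis="both"`` applies a full DFT along the height axis as well (keeping
the Hermitian reduction on the width axis only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _skimage_resize

from .complex_core import ComplexTensor
from .exceptions import DegenerateInputError, GeometryError

__all__ = [
    "RealImage",
    "ComplexImage",
    "normalize_image",
    "resize_image",
    "dft_matrix",
    "to_complex_domain",
    "reconstruct_real",
    "hermitian_width",
]

#: A complex image is carried the same way as any complex tensor.
ComplexImage = ComplexTensor


@dataclass(frozen=True)
class RealImage:
    """An H x W x C real image with a normalization provenance flag."""

    pixels: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise GeometryError(f"expected H x W x C pixels, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)


def _as_pixels(img) -> np.ndarray:
    if isinstance(img, RealImage):
        return img.pixels
    px = np.asarray(img, dtype=float)
    return px[:, :, None] if px.ndim == 2 else px


def hermitian_width(width: int) -> int:
    """Number of non-redundant DFT coefficients of a real signal of length ``width``."""
    return width // 2 + 1


def normalize_image(img) -> RealImage:
    """Standardize an image: subtract its mean, divide by its standard deviation.

    Statistics are computed over all pixels (all channels) of the image with
    the population (divisor-N) convention. Raises
    :class:`DegenerateInputError` for a constant image.
    """
    px = _as_pixels(img)
    mu = px.mean()
    sd = px.std()
    if sd == 0:
        raise DegenerateInputError("constant image: standard deviation is zero")
    return RealImage((px - mu) / sd, normalized=True)


def resize_image(img, side: int) -> RealImage:
    """Resize to ``side`` x ``side`` with bilinear interpolation (antialiased).

    Antialiasing is applied when downsampling (scikit-image default).
    """
    if side < 1:
        raise GeometryError(f"side must be >= 1, got {side}")
    px = _as_pixels(img)
    if px.shape[0] == side and px.shape[1] == side:
        out = px.copy()
    else:
        out = _skimage_resize(
            px, (side, side, px.shape[2]), order=1, anti_aliasing=None,
            preserve_range=True, mode="reflect",
        )
    normalized = img.normalized if isinstance(img, RealImage) else False
    return RealImage(out, normalized=normalized)


def dft_matrix(N: int) -> np.ndarray:
    """The N x N Fourier/Vandermonde matrix ``F[j, k] = exp(-2*pi*i*j*k/N)``.

    Symmetric, unit-modulus entries, and unitary up to scale:
    ``F @ conj(F) / N = I``.
    """
    if N < 1:
        raise GeometryError(f"matrix order must be >= 1, got {N}")
    jk = np.outer(np.arange(N), np.arange(N))
    return np.exp(-2j * np.pi * jk / N)


def to_complex_domain(img, axis: str = "width") -> ComplexImage:
    """Convert a (normalized) real image into the complex domain.

    Each row of each channel is multiplied by the Fourier matrix of order W
    and only the first ``floor(W/2) + 1`` coefficients are retained (the
    non-redundant Hermitian half of a real signal's spectrum).
    With ``axis="both"`` a full (unreduced) DFT is additionally applied
    along the height axis.

    Parameters
    ----------
    img : RealImage or array
        H x W x C image. A :class:`RealImage` must carry ``normalized=True``.
    axis : {"width", "both"}
        Transform the width axis only (default) or both spatial axes.

    Returns
    -------
    ComplexImage with component shapes H x W' x C, W' = floor(W/2) + 1.
    """
    if isinstance(img, RealImage) and not img.normalized:
        raise DegenerateInputError("normalize_image must be applied before conversion")
    if axis not in ("width", "both"):
        raise GeometryError(f"axis must be 'width' or 'both', got {axis!r}")
    px = _as_pixels(img)
    h, w, c = px.shape
    F = dft_matrix(w)
    keep = hermitian_width(w)
    # (H, W, C) x (W, W') along the width axis
    spec = np.tensordot(px, F[:, :keep], axes=([1], [0]))  # -> (H, C, W')
    spec = np.moveaxis(spec, 2, 1)  # -> (H, W', C)
    if axis == "both":
        Fh = dft_matrix(h)
        spec = np.tensordot(Fh, spec, axes=([1], [0]))
    return ComplexImage(np.ascontiguousarray(spec.real), np.ascontiguousarray(spec.imag))


def reconstruct_real(cimg: ComplexImage, W: int, axis: str = "width") -> RealImage:
    """Invert :func:`to_complex_domain` for an original width ``W``.

    The full spectrum is rebuilt by conjugate symmetry and inverted with the
    conjugate Fourier matrix; the result matches the original real image to
    machine precision (used as a lossless-reduction verification aid).
    """
    keep = hermitian_width(W)
    spec = cimg.to_complex()
    if spec.shape[1] != keep:
        raise GeometryError(
            f"component width {spec.shape[1]} inconsistent with original width {W}"
        )
    if axis == "both":
        h = spec.shape[0]
        Fh_inv = np.conj(dft_matrix(h)) / h
        spec = np.tensordot(Fh_inv, spec, axes=([1], [0]))
    full = np.empty((spec.shape[0], W, spec.shape[2]), dtype=complex)
    full[:, :keep, :] = spec
    if W > 1:
        full[:, keep:, :] = np.conj(spec[:, 1 : W - keep + 1, :][:, ::-1, :])
    F_inv = np.conj(dft_matrix(W)) / W
    out = np.tensordot(full, F_inv.T, axes=([1], [0]))  # (H, C, W)
    out = np.moveaxis(out, 2, 1)
    return RealImage(out.real, normalized=True)
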