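"""Paired complex- and real-valued network construction with parameter parity.

The comparison rests on two networks with the same layer schedule —
three (conv, pool, activation) blocks, three dense layers, and a 2-unit
output — differing only in their numeric domain. Fairness requires an
equivalent number of trainable parameters, counted in real scalars (one
complex weight = two scalars). Because the Hermitian reduction halves the
complex network's input width (and hence its flatten size), equal widths do
not give equal counts; :func:`matched_real_spec` finds a single width scale
factor for the real network by bisection so that the totals agree within a
configured tolerance.

Layer widths are configurable; the shipped defaults are a desk-scale pair
(32 x 32 inputs) used throughout the tests, and :func:`paper_scale_pair`
provides a 224 x 224 configuration of the same shape family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import complex_core as cc
from .complex_core import ComplexTensor, count_parameters
from .domain_transform import hermitian_width, to_complex_domain
from .exceptions import ConfigurationError

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ParityReport",
    "build_network",
    "parity_report",
    "matched_real_spec",
    "default_pair",
    "paper_scale_pair",
    "layer_specs",
    "Network",
    "REFERENCE_PARAMETER_LEDGER",
]

#: Per-layer trainable-parameter counts reported for the original
#: full-scale network pair (complex counts in complex units, real counts in
#: scalars). Kept as a transcription; the shipped architectures are not an
#: inversion of it (kernel/channel sizes are not derivable from the totals).
REFERENCE_PARAMETER_LEDGER: dict[str, tuple[int, int]] = {
    "Conv1": (71940, 290400),
    "Conv2": (186608, 285144),
    "Conv3": (725760, 1492992),
    "Fully Connected 1": (169600, 359552),
    "Fully Connected 2": (1200, 1200),
    "Fully Connected 3": (500, 500),
    "Output": (2, 2),
}


@dataclass(frozen=True)
class LayerSpec:
    """Resolved geometry of one layer, sufficient for parameter counting."""

    kind: str  # conv | dense | pool | act | flatten | readout
    domain: str  # complex | real
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 0
    in_features: int = 0
    out_features: int = 0
    bias: bool = True


@dataclass
class ArchitectureSpec:
    """Declarative description of one network.

    ``conv`` lists output channels of the three conv blocks, ``dense`` the
    widths of the three fully connected layers; the output layer always has
    2 units (normal vs abnormal).
    """

    domain: str = "complex"
    input_size: int = 32
    in_channels: int = 3
    conv: tuple[int, ...] = (8, 16, 32)
    dense: tuple[int, ...] = (64, 32, 16)
    kernel: int = 3
    pool: int = 2
    padding: int = 1
    bias: bool = True
    n_classes: int = 2
    transform: str = "dft"  # dft | identity (complex networks only)
    transform_axis: str = "width"
    activation: str = "zrelu"  # zrelu | split (complex networks only)
    readout: str = "magnitude"  # magnitude | real (complex networks only)

    def __post_init__(self):
        if self.domain not in ("complex", "real"):
            raise ConfigurationError(f"unknown domain {self.domain!r}")
        if self.input_size < 4 or self.in_channels < 1:
            raise ConfigurationError("invalid input geometry")
        if len(self.conv) == 0 or len(self.dense) == 0:
            raise ConfigurationError("conv and dense schedules must be non-empty")
        if any(c < 1 for c in self.conv) or any(d < 1 for d in self.dense):
            raise ConfigurationError("layer widths must be positive")
        self.conv = tuple(int(c) for c in self.conv)
        self.dense = tuple(int(d) for d in self.dense)

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["conv"] = tuple(raw.get("conv", ()))
        raw["dense"] = tuple(raw.get("dense", ()))
        return cls(**raw)


@dataclass(frozen=True)
class ParityReport:
    """Real-scalar parameter totals of a network pair and their ratio."""

    complex_total_real_scalars: int
    real_total: int
    ratio: float
    tolerance: float
    passes: bool


def _spatial_schedule(spec: ArchitectureSpec) -> tuple[int, int]:
    """Spatial extent after the conv/pool stack (h, w)."""
    h = spec.input_size
    reduced = spec.domain == "complex" and spec.transform == "dft"
    w = hermitian_width(spec.input_size) if reduced else spec.input_size
    for _ in spec.conv:
        # conv keeps the extent (stride 1, same padding with odd kernel)
        h = (h + 2 * spec.padding - spec.kernel) + 1
        w = (w + 2 * spec.padding - spec.kernel) + 1
        h, w = h // spec.pool, w // spec.pool
        if h < 1 or w < 1:
            raise ConfigurationError("spatial extent collapsed before the dense stack")
    return h, w


def layer_specs(spec: ArchitectureSpec) -> list[LayerSpec]:
    """Expand an :class:`ArchitectureSpec` into resolved :class:`LayerSpec` rows."""
    rows: list[LayerSpec] = []
    d = spec.domain
    in_ch = spec.in_channels
    for out_ch in spec.conv:
        rows.append(LayerSpec("conv", d, in_channels=in_ch, out_channels=out_ch,
                              kernel=spec.kernel, bias=spec.bias))
        rows.append(LayerSpec("pool", d))
        rows.append(LayerSpec("act", d))
        in_ch = out_ch
    h, w = _spatial_schedule(spec)
    rows.append(LayerSpec("flatten", d))
    in_f = in_ch * h * w
    for out_f in spec.dense:
        rows.append(LayerSpec("dense", d, in_features=in_f, out_features=out_f,
                              bias=spec.bias))
        rows.append(LayerSpec("act", d))
        in_f = out_f
    rows.append(LayerSpec("dense", d, in_features=in_f, out_features=spec.n_classes,
                          bias=spec.bias))
    rows.append(LayerSpec("readout", d))
    return rows


def total_parameters(spec: ArchitectureSpec, unit: str = "real_scalar") -> int:
    return sum(count_parameters(row, unit=unit) for row in layer_specs(spec)
               if row.kind in ("conv", "dense"))


class Network:
    """A sequential model mapping an input batch to 2 real class scores.

    Complex networks prepend the real-to-complex conversion and end with the
    magnitude readout; real networks consume the normalized image directly.
    Inputs are (N, C, H, W) float arrays.
    """

    def __init__(self, spec: ArchitectureSpec, layers: list):
        self.spec = spec
        self.layers = layers

    def parameters(self) -> list[cc.Parameter]:
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def _to_complex_batch(self, x: np.ndarray) -> ComplexTensor:
        if self.spec.transform == "identity":
            return ComplexTensor(x, np.zeros_like(x))
        # DFT along the width axis of each row/channel; (N, C, H, W) layout.
        # The spectrum is scaled by 1/sqrt(W) (unitary normalization) so that
        # complex-layer inputs share the scale of the normalized real inputs;
        # the library-level to_complex_domain keeps the raw Vandermonde product.
        from .domain_transform import dft_matrix

        w = x.shape[3]
        F = dft_matrix(w)[:, : hermitian_width(w)] / np.sqrt(w)
        spec = np.tensordot(x, F, axes=([3], [0]))  # (N, C, H, W')
        return ComplexTensor(np.ascontiguousarray(spec.real),
                             np.ascontiguousarray(spec.imag))

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self._to_complex_batch(np.asarray(x, dtype=float)) \
            if self.spec.domain == "complex" else np.asarray(x, dtype=float)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    __call__ = forward

    def backward(self, grad_scores: np.ndarray) -> None:
        g = grad_scores
        for layer in reversed(self.layers):
            g = layer.backward(g)


def build_network(spec: ArchitectureSpec, seed: int = 0, bias_init: float = 0.1) -> Network:
    """Instantiate the network described by ``spec`` with seeded initialization."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7 if spec.domain == "complex" else 11]))
    layers: list = []
    d = spec.domain
    conv_cls = cc.ComplexConv2d if d == "complex" else cc.RealConv2d
    pool_cls = cc.ComplexAvgPool2d if d == "complex" else cc.RealAvgPool2d
    if d == "complex":
        def act_cls():
            return cc.ComplexReLU(mode=spec.activation)
    else:
        act_cls = cc.RealReLU
    flat_cls = cc.ComplexFlatten if d == "complex" else cc.RealFlatten
    dense_cls = cc.ComplexLinear if d == "complex" else cc.RealLinear
    in_ch = spec.in_channels
    for out_ch in spec.conv:
        layers.append(conv_cls(in_ch, out_ch, spec.kernel, stride=1,
                               padding=spec.padding, bias=spec.bias, rng=rng))
        layers.append(pool_cls(spec.pool))
        layers.append(act_cls())
        in_ch = out_ch
    h, w = _spatial_schedule(spec)
    layers.append(flat_cls())
    in_f = in_ch * h * w
    for out_f in spec.dense:
        layers.append(dense_cls(in_f, out_f, bias=spec.bias, rng=rng))
        layers.append(act_cls())
        in_f = out_f
    layers.append(dense_cls(in_f, spec.n_classes, bias=spec.bias, rng=rng))
    if d == "complex":
        layers.append(cc.MagnitudeReadout() if spec.readout == "magnitude"
                      else cc.RealPartReadout())
    else:
        layers.append(cc.ScoreReadout())
    if bias_init:
        # small positive bias keeps the (z)ReLU gates open at initialization
        for layer in layers:
            for p in layer.parameters():
                if p.name.endswith("bias"):
                    p.real += bias_init
                    if p.imag is not None:
                        p.imag += bias_init
    return Network(spec, layers)


def parity_report(cspec: ArchitectureSpec, rspec: ArchitectureSpec,
                  tolerance: float = 0.10) -> ParityReport:
    """Compare real-scalar parameter totals of a complex/real pair."""
    c_total = total_parameters(cspec, unit="real_scalar")
    r_total = total_parameters(rspec, unit="real_scalar")
    ratio = c_total / r_total
    return ParityReport(c_total, r_total, ratio, tolerance,
                        bool(1 - tolerance <= ratio <= 1 + tolerance))


def _scaled_real_spec(cspec: ArchitectureSpec, scale: float) -> ArchitectureSpec:
    return ArchitectureSpec(
        domain="real",
        input_size=cspec.input_size,
        in_channels=cspec.in_channels,
        conv=tuple(max(1, round(c * scale)) for c in cspec.conv),
        dense=tuple(max(1, round(d * scale)) for d in cspec.dense),
        kernel=cspec.kernel,
        pool=cspec.pool,
        padding=cspec.padding,
        bias=cspec.bias,
        n_classes=cspec.n_classes,
    )


def matched_real_spec(cspec: ArchitectureSpec, tolerance: float = 0.10) -> ArchitectureSpec:
    """Real-domain twin of ``cspec`` with matched real-scalar parameter total.

    All hidden widths are scaled by one factor found by bisection; input
    channels and the 2-unit output stay fixed. Raises
    :class:`ConfigurationError` if no scale lands within the tolerance
    (possible only for extremely narrow networks where rounding dominates).
    """
    target = total_parameters(cspec, unit="real_scalar")
    lo, hi = 0.5, 3.0
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        spec = _scaled_real_spec(cspec, mid)
        total = total_parameters(spec, unit="real_scalar")
        ratio = target / total
        if best is None or abs(ratio - 1) < abs(best[0] - 1):
            best = (ratio, spec)
        if total < target:
            lo = mid
        else:
            hi = mid
    ratio, spec = best
    if not (1 - tolerance <= ratio <= 1 + tolerance):
        raise ConfigurationError(
            f"could not match parameter totals within {tolerance:.0%} (best ratio {ratio:.3f})"
        )
    return spec


def default_pair(input_size: int = 32, conv: tuple[int, ...] = (8, 16, 32),
                 dense: tuple[int, ...] = (64, 32, 16)) -> tuple[ArchitectureSpec, ArchitectureSpec]:
    """The shipped desk-scale pair: complex spec plus its parity-matched real twin."""
    cspec = ArchitectureSpec(domain="complex", input_size=input_size,
                             conv=conv, dense=dense)
    return cspec, matched_real_spec(cspec)


def paper_scale_pair() -> tuple[ArchitectureSpec, ArchitectureSpec]:
    """A 224 x 224 configuration of the same family (not exercised by tests)."""
    cspec = ArchitectureSpec(domain="complex", input_size=224,
                             conv=(16, 32, 64), dense=(256, 64, 32))
    return cspec, matched_real_spec(cspec)
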