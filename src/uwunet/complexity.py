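"""Analytic parameter and FLOP accounting for architecture specs.

Green-AI bookkeeping: both quantities are computed purely arithmetically
from an :class:`~uwunet.architectures.ArchitectureSpec` — no network is
built and nothing is measured at runtime — so the numbers are
hardware-agnostic and exactly reproducible.

Parameter closed forms (all convolutions biased, batch norm contributes a
learned scale and shift per channel):

* ``DoubleConv(a -> b)``: ``9ab + 9b^2 + 6b``
* ``TransposedConv2x2(a -> b)``: ``4ab + b``
* ``OutConv 1x1 (a -> c)``: ``ac + c``

FLOP convention (forward pass, batch 1, inference-mode batch norm):

* (transposed) convolution: ``2 * K^2 * C_in * C_out * H_out * W_out``
  (one multiply-accumulate = 2 FLOPs, counted at the *output* resolution),
  plus 1 FLOP per output element for the bias;
* batch norm: 2 FLOPs per element; activation: 1 FLOP per element;
* 2x2 max pooling: 3 comparisons per output element;
* skip concatenation and tensor copies: 0 FLOPs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .architectures import ArchitectureSpec

__all__ = ["LayerCost", "ComplexityReport", "count_parameters", "count_flops", "report"]

GIGA = 1e9
MEGA = 1e6


@dataclass(frozen=True)
class LayerCost:
    """One row of a complexity report."""
    label: str
    params: int
    flops: float


@dataclass(frozen=True)
class ComplexityReport:
    """Per-layer and total parameter/FLOP accounting at a given input size."""
    name: str
    layers: tuple[LayerCost, ...]
    total_params: int
    total_flops: float
    input_size: tuple[int, int]

    @property
    def total_params_m(self) -> float:
        """Total parameters in millions, rounded to 3 decimals (table format)."""
        return round(self.total_params / MEGA, 3)

    @property
    def total_flops_g(self) -> float:
        """Total FLOPs in G (1e9), rounded to 3 decimals (table format)."""
        return round(self.total_flops / GIGA, 3)


def _double_conv_layers(prefix: str, a: int, b: int, h: int, w: int) -> list[LayerCost]:
    """Conv(a->b)+BN+act, Conv(b->b)+BN+act at output resolution h x w."""
    elems = b * h * w
    return [
        LayerCost(f"{prefix}.conv1", 9 * a * b + b, 2 * 9 * a * b * h * w + elems),
        LayerCost(f"{prefix}.bn1", 2 * b, 2 * elems),
        LayerCost(f"{prefix}.act1", 0, elems),
        LayerCost(f"{prefix}.conv2", 9 * b * b + b, 2 * 9 * b * b * h * w + elems),
        LayerCost(f"{prefix}.bn2", 2 * b, 2 * elems),
        LayerCost(f"{prefix}.act2", 0, elems),
    ]


def _layer_table(spec: ArchitectureSpec, height: int, width: int) -> list[LayerCost]:
    spec.check_input_size(height, width)
    rows: list[LayerCost] = []
    d = spec.depth
    h, w = height, width
    rows += _double_conv_layers("inc", spec.in_channels, spec.width(0), h, w)
    for k in range(1, d + 1):
        a, b = spec.width(k - 1), spec.width(k)
        h, w = h // 2, w // 2
        rows.append(LayerCost(f"down{k}.pool", 0, 3 * a * h * w))
        rows += _double_conv_layers(f"down{k}", a, b, h, w)
    for i, k in enumerate(range(d, 0, -1), start=1):
        a, b = spec.width(k), spec.width(k - 1)
        h, w = h * 2, w * 2
        # transposed conv counted at output resolution, per the fixed convention
        rows.append(LayerCost(f"up{i}.upconv", 4 * a * b + b,
                              2 * 4 * a * b * h * w + b * h * w))
        rows += _double_conv_layers(f"up{i}", 2 * b, b, h, w)
    c = spec.out_channels
    rows.append(LayerCost("outc", spec.width(0) * c + c,
                          2 * spec.width(0) * c * h * w + c * h * w))
    return rows


def count_parameters(spec: ArchitectureSpec) -> int:
    """Exact trainable-scalar count of the network described by ``spec``.

    Equals the enumeration of ``build_model(spec)``'s trainable arrays.
    """
    # input size is irrelevant to parameters; use the smallest legal one
    s = 2 ** spec.depth
    return sum(r.params for r in _layer_table(spec, s, s))


def count_flops(spec: ArchitectureSpec, height: int, width: int) -> float:
    """Forward-pass FLOPs at ``height x width`` under the fixed convention.

    Raises ``ValueError`` if the input size is not divisible by
    ``2**spec.depth``.
    """
    return float(sum(r.flops for r in _layer_table(spec, height, width)))


def report(spec: ArchitectureSpec, height: int, width: int) -> ComplexityReport:
    """Per-layer breakdown whose totals equal :func:`count_parameters` and
    :func:`count_flops`."""
    rows = tuple(_layer_table(spec, height, width))
    return ComplexityReport(
        name=spec.name,
        layers=rows,
        total_params=sum(r.params for r in rows),
        total_flops=float(sum(r.flops for r in rows)),
        input_size=(height, width),
    )
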