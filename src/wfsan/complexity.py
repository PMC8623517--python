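"""Closed-form parameter and FLOP accounting for the block types.

The three block families compared are the mini-grid network (two dense
convolution stages), the ghost extension block (dense stage + bias-free
depthwise cheap stage) and its spatial-attention variant (which adds
only the 2-in/1-out merge convolution, i.e. 2k² weights and 4k²·H·W
FLOPs).  Counts follow the convention that the "+1" terms are the
biases of the dense stage, the cheap depthwise stage is bias-free, and
one multiply-accumulate is two FLOPs.

``model_param_census`` enumerates an instantiated network layer by
layer so the analytic formulas can be cross-checked against real
weight tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import WFSAN, NetworkConfig

__all__ = [
    "MINI_GRID",
    "GHOST",
    "ATTENTION_GHOST",
    "ComplexityInputs",
    "ComplexityReport",
    "param_count",
    "flop_count",
    "model_param_census",
]

MINI_GRID = "mini_grid"
GHOST = "ghost"
ATTENTION_GHOST = "attention_ghost"
KINDS = (MINI_GRID, GHOST, ATTENTION_GHOST)


@dataclass
class ComplexityInputs:
    """Symbols of the closed-form expressions.

    N: input channels; C: number of filters of the first (dense) stage;
    M: output channels of the second stage (mini-grid only); k: kernel
    size; H, W: feature-map spatial size.
    """

    N: int = 32
    C: int = 32
    M: int = 32
    k: int = 3
    H: int = 48
    W: int = 48

    def __post_init__(self) -> None:
        for name in ("N", "C", "M", "k", "H", "W"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass
class ComplexityReport:
    block_kind: str
    parameters: int
    flops: int


def param_count(kind: str, inputs: ComplexityInputs) -> int:
    """Exact trainable-parameter count of one block."""
    n, c, m, k = inputs.N, inputs.C, inputs.M, inputs.k
    if kind == MINI_GRID:
        return (n * k**2 + 1) * c + (c * k**2 + 1) * m
    if kind == GHOST:
        return (n * k**2 + 1) * c + c * k**2
    if kind == ATTENTION_GHOST:
        return (n * k**2 + 1) * c + c * k**2 + 2 * k**2
    raise ValueError(f"unknown block kind {kind!r}")


def flop_count(kind: str, inputs: ComplexityInputs) -> int:
    """Exact FLOP count of one block (1 MAC = 2 FLOPs)."""
    n, c, m, k = inputs.N, inputs.C, inputs.M, inputs.k
    hw = inputs.H * inputs.W
    if kind == MINI_GRID:
        return 2 * k**2 * c * hw * (n + m)
    if kind == GHOST:
        return 2 * k**2 * c * hw * (n + 1)
    if kind == ATTENTION_GHOST:
        return 2 * k**2 * c * hw * (n + 1) + 4 * k**2 * hw
    raise ValueError(f"unknown block kind {kind!r}")


def report(kind: str, inputs: ComplexityInputs) -> ComplexityReport:
    return ComplexityReport(kind, param_count(kind, inputs), flop_count(kind, inputs))


def model_param_census(config: NetworkConfig, model: WFSAN | None = None) -> dict:
    """Per-layer trainable-parameter counts of an instantiated network.

    Returns ``{"layers": {name: count}, "blocks": {name: count},
    "total": int}``.  Block subtotals (primary + cheap + attention
    weights) equal the analytic :func:`param_count` values for the
    matching kind and symbols.
    """
    if model is None:
        model = WFSAN(config)
    layers: dict[str, int] = {}
    blocks: dict[str, int] = {}
    for name, layer in model.named_layers():
        n = sum(p.size for p in layer.params())
        if n or layer.params():
            layers[name] = n
        if hasattr(layer, "kind") and hasattr(layer, "spec"):
            blocks[name] = n
    return {"layers": layers, "blocks": blocks, "total": sum(layers.values())}
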