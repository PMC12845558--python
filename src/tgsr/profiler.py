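"""Exact parameter and multiply-accumulate budgets for the network variants.

Parameters are counted by enumerating every trainable array in the built
model.  MACs are counted per layer for a one-sample forward pass with a
mainstream profiler convention: a convolution costs
``(k^2 * C_in / groups + 1) * C_out * H_out * W_out`` (the +1 is the
accumulate of the bias / normalisation-shift slot, counted whether or not
the conv carries an explicit bias), a linear layer ``(C_in + 1) * C_out``,
batch normalisation two operations per output element, activations one per
element, pooling one per pooled input element; bare tensor ops (residual
adds, attention gating multiplies, concatenation) are free.  Reported FLOPs
equal MACs, the usual convention of CNN profilers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .net import NetworkVariant, YCrCbMix, build_model
from .nn.tensor import Tensor

__all__ = ["BudgetReport", "count_params", "count_macs", "layer_breakdown",
           "budget_table", "reduction_percent"]


@dataclass
class BudgetReport:
    """Parameter/MAC budget of one variant, with a per-layer breakdown."""

    variant: NetworkVariant
    params_exact: int
    macs_exact: int
    breakdown: list[tuple[str, int, int]] = field(repr=False, default_factory=list)

    @property
    def params_M(self) -> float:
        return round(self.params_exact / 1e6, 3)

    @property
    def flops_G(self) -> float:
        return round(self.macs_exact / 1e9, 3)


def count_params(net: nn.Module) -> int:
    """Total trainable scalars (conv/linear weights+biases, BN scale+shift)."""
    return sum(p.data.size for p in net.parameters())


def _elems(shape) -> int:
    """Per-sample element count of an activation shape."""
    return int(np.prod(shape[1:]))


def _layer_macs(mod: nn.Module) -> int | None:
    """MACs of a leaf module per the counting convention; None if container."""
    if isinstance(mod, nn.Conv2d):
        ho, wo = mod.out_shape[2], mod.out_shape[3]
        # one extra accumulate per output element (bias / BN-shift slot)
        return (mod.kernel ** 2 * mod.cin // mod.groups + 1) * mod.cout * ho * wo
    if isinstance(mod, nn.Linear):
        return mod.cin * mod.cout + mod.cout
    if isinstance(mod, nn.BatchNorm2d):
        return 2 * _elems(mod.out_shape)
    if isinstance(mod, (nn.ReLU, nn.GELU, nn.Hardswish, nn.Hardsigmoid,
                        nn.Sigmoid)):
        return _elems(mod.out_shape)
    if isinstance(mod, (nn.MaxPool2x2, nn.GlobalAvgPool,
                        nn.DirectionalAvgPool)):
        return _elems(mod.in_shape)
    if isinstance(mod, YCrCbMix):
        return 9 * mod.out_shape[2] * mod.out_shape[3]
    if isinstance(mod, (nn.Identity, nn.Dropout)):
        return 0
    return None  # container


def layer_breakdown(net: nn.Module, input_size: int | None = None
                    ) -> list[tuple[str, int, int]]:
    """Per-leaf-module (name, params, MACs) for a one-sample forward."""
    if input_size is None:
        input_size = getattr(getattr(net, "variant", None), "input_size", 224)
    was_training = net.training
    net.eval()
    net(Tensor(np.zeros((1, 3, input_size, input_size), np.float32)))
    if was_training:
        net.train()
    rows = []
    for name, mod in net.named_modules():
        macs = _layer_macs(mod)
        if macs is None:
            continue
        params = sum(p.data.size for p in mod._params.values())
        if params or macs:
            rows.append((name, params, macs))
    return rows


def count_macs(net: nn.Module, input_size: int | None = None) -> int:
    """One-sample forward multiply-accumulate count (see module docstring)."""
    return sum(m for _, _, m in layer_breakdown(net, input_size))


def profile(variant: NetworkVariant | str, *, seed: int = 0) -> BudgetReport:
    net = build_model(variant, seed=seed)
    rows = layer_breakdown(net)
    report = BudgetReport(net.variant, count_params(net),
                          sum(m for _, _, m in rows), rows)
    assert report.params_exact == sum(p for _, p, _ in rows)
    return report


def reduction_percent(base: BudgetReport, other: BudgetReport) -> float:
    """Parameter reduction of ``other`` relative to ``base``, in percent.

    Computed from the budgets at their reporting precision (3 decimals in
    millions), matching how such percentages are quoted alongside budget
    tables.
    """
    return 100.0 * (base.params_M - other.params_M) / base.params_M


def budget_table(variants: list[NetworkVariant | str] | None = None
                 ) -> list[BudgetReport]:
    if variants is None:
        variants = ["baseline", "residual", "gelu", "ica", "tgsr"]
    return [profile(v) for v in variants]
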