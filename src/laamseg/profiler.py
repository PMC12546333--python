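"""Analytic parameter/MAC profiler.

Counting convention (frozen for every model in the package): one
multiply-accumulate per kernel tap, convolution and fully connected layers
only; normalization, activation, pooling and elementwise ops are excluded;
GFLOPs = 2 * MACs / 1e9.  Complexity is an architecture property, so the
profiler walks layer shapes without executing the network; an independent
hook-based counter that measures the shapes actually executed during a real
forward pass is provided as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .nn import Module


def count_conv_macs(in_c: int, out_c: int, kernel: int, out_h: int, out_w: int,
                    groups: int = 1) -> int:
    """Closed-form MAC count of a convolution: out_h*out_w*out_c*(in_c/groups)*k^2."""
    if min(in_c, out_c, kernel, groups) <= 0 or out_h < 0 or out_w < 0:
        raise ValueError("arguments must be positive (spatial extents non-negative)")
    if in_c % groups or out_c % groups:
        raise ValueError("groups must divide in_c and out_c")
    return out_h * out_w * out_c * (in_c // groups) * kernel ** 2


@dataclass
class ComplexityReport:
    params: int
    macs: int
    gflops: float
    per_layer: list = field(default_factory=list)  # (name, params, macs)

    def table(self) -> str:
        lines = [f"{'layer':<40s}{'params':>12s}{'MACs':>16s}"]
        for name, p, m in self.per_layer:
            lines.append(f"{name:<40s}{p:>12d}{m:>16d}")
        lines.append(f"{'TOTAL':<40s}{self.params:>12d}{self.macs:>16d}")
        lines.append(f"GFLOPs (2*MACs/1e9): {self.gflops:.2f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "macs": self.macs,
                           "gflops": self.gflops,
                           "per_layer": [list(e) for e in self.per_layer]}, indent=2)


def profile(model_or_module, input_shape) -> ComplexityReport:
    """Analytic profile of any module at ``input_shape`` = (C, H, W).

    For a full :class:`~laamseg.model.SegModel`, pass (3, H, W) (or None to
    use the configured input size).
    """
    m = model_or_module
    if hasattr(m, "cfg") and hasattr(m, "complexity") and not isinstance(input_shape, tuple):
        entries = m.complexity(None)
    elif hasattr(m, "complexity"):
        res = m.complexity(input_shape)
        entries = res if isinstance(res, list) else res[1]
    else:
        raise TypeError(f"{type(m).__name__} does not expose complexity()")
    params = int(sum(p for _, p, _ in entries))
    macs = int(sum(f for _, _, f in entries))
    return ComplexityReport(params=params, macs=macs, gflops=2.0 * macs / 1e9,
                            per_layer=list(entries))


def profile_runtime(module: Module, input_shape) -> int:
    """Hook-based MAC count: run a real forward pass on a zero input of
    ``input_shape`` = (C, H, W) and sum the convolution MACs actually
    executed.  Independent of the analytic shape-walk."""
    x = T.Tensor(np.zeros((1, *input_shape), dtype=np.float32))
    was_training = module.training
    module.eval()
    try:
        with T.no_grad(), T.count_macs() as log:
            module(x)
    finally:
        module.train(was_training)
    return int(sum(m // n for n, m in log))
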