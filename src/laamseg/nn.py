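"""Layer library on top of the autodiff engine.

Conventions follow the YOLOv5 house style: every convolution is followed by
batch normalization and SiLU unless stated otherwise, parameters are
Kaiming-uniform initialized, and construction is deterministic under
:func:`init_seed`.

Each module additionally knows its own analytic complexity
(``complexity(in_shape) -> (out_shape, entries)`` with per-layer parameter and
multiply-accumulate counts) so the profiler can walk a model without running
it.  Only convolution/linear MACs are counted, matching the frozen GFLOPs
convention (2 * MACs / 1e9, normalization/activation/pooling excluded).
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

_RNG = np.random.default_rng(0)


@contextlib.contextmanager
def init_seed(seed: int):
    """Make module construction (weight initialization) deterministic."""
    global _RNG
    prev = _RNG
    _RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _RNG = prev


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def _kaiming_uniform(shape, fan_in, rng=None):
    rng = rng or _RNG
    bound = math.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Module:
    """Base class: attribute-scanned parameter registry, train/eval mode."""

    def __init__(self):
        self.training = True

    # -------------------------------------------------------------- registry
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in getattr(self, "_buffers", {}).items():
            yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: v.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())  # named_buffers yields live arrays
        for k, v in d.items():
            if k in params:
                params[k].data[...] = v
            elif k in buffers:
                buffers[k][...] = v
            else:
                raise KeyError(f"unknown state entry {k!r}")

    def train(self, mode: bool = True):
        self.training = mode
        for _, c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # ------------------------------------------------------------ complexity
    def complexity(self, in_shape):
        """Return (out_shape, entries); in_shape is (C, H, W) for one image."""
        raise NotImplementedError(type(self).__name__)

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel=1, stride=1, padding=None,
                 dilation=1, groups=1, bias=True):
        super().__init__()
        if kernel % 2 == 0 and padding is None:
            raise ValueError("kernel size must be odd for implicit 'same' padding")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide in_channels and out_channels")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.dilation, self.groups = kernel, stride, dilation, groups
        # 'same' padding for stride 1; yolo-style k//2*d otherwise
        self.padding = dilation * (kernel - 1) // 2 if padding is None else padding
        fan_in = in_channels // groups * kernel * kernel
        self.weight = Parameter(_kaiming_uniform((out_channels, in_channels // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation, groups=self.groups)

    def out_hw(self, h, w):
        k, s, d, p = self.kernel, self.stride, self.dilation, self.padding
        return ((h + 2 * p - d * (k - 1) - 1) // s + 1,
                (w + 2 * p - d * (k - 1) - 1) // s + 1)

    def complexity(self, in_shape):
        c, h, w = in_shape
        oh, ow = self.out_hw(h, w)
        macs = oh * ow * self.out_channels * (self.in_channels // self.groups) * self.kernel ** 2
        params = self.weight.data.size + (self.bias.data.size if self.bias is not None else 0)
        return (self.out_channels, oh, ow), [("conv", params, macs)]


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-3, momentum=0.03):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }

    def forward(self, x):
        if self.training and T.is_grad_enabled():
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1 - self.momentum
            rm += self.momentum * mu.data.reshape(-1)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            rv *= 1 - self.momentum
            rv += self.momentum * var.data.reshape(-1) * n / max(n - 1, 1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
        xn = (x - mu) / T.sqrt(var + self.eps)
        gamma = T.reshape(self.weight, (1, -1, 1, 1))
        beta = T.reshape(self.bias, (1, -1, 1, 1))
        return xn * gamma + beta

    def complexity(self, in_shape):
        return in_shape, [("bn", self.weight.data.size + self.bias.data.size, 0)]


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)

    def complexity(self, in_shape):
        return in_shape, []


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)

    def complexity(self, in_shape):
        return in_shape, []


class Identity(Module):
    def forward(self, x):
        return x

    def complexity(self, in_shape):
        return in_shape, []


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def complexity(self, in_shape):
        entries = []
        for i, m in enumerate(self.mods):
            in_shape, sub = m.complexity(in_shape)
            entries += [(f"{i}.{n}", p, f) for n, p, f in sub]
        return in_shape, entries


class MaxPool2dSame(Module):
    """Stride-1 same-padded max pool (SPP pyramid branch)."""

    def __init__(self, kernel):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return T.maxpool2d_same(x, self.kernel)

    def complexity(self, in_shape):
        return in_shape, []


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return T.upsample_nearest(x, self.scale)

    def complexity(self, in_shape):
        c, h, w = in_shape
        return (c, h * self.scale, w * self.scale), []


class ConvBnAct(Module):
    """Conv + BatchNorm + activation (the YOLOv5 'Conv' block)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, d=1, g=1, act=True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, d, g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))

    def complexity(self, in_shape):
        out, e1 = self.conv.complexity(in_shape)
        _, e2 = self.bn.complexity(out)
        return out, e1 + e2


class SGD:
    """SGD with momentum, optional Nesterov and decoupled parameter groups."""

    def __init__(self, params, lr, momentum=0.937, weight_decay=0.0, nesterov=True):
        self.param_groups = [{"params": list(params), "lr": lr,
                              "momentum": momentum, "weight_decay": weight_decay}]
        self.nesterov = nesterov
        self._v = {}

    def add_group(self, params, lr, momentum=0.937, weight_decay=0.0):
        self.param_groups.append({"params": list(params), "lr": lr,
                                  "momentum": momentum, "weight_decay": weight_decay})

    def zero_grad(self):
        for g in self.param_groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        for g in self.param_groups:
            for p in g["params"]:
                if p.grad is None:
                    continue
                d = p.grad.astype(np.float32)
                if g["weight_decay"]:
                    d = d + g["weight_decay"] * p.data
                v = self._v.get(id(p))
                if v is None:
                    v = np.zeros_like(p.data)
                    self._v[id(p)] = v
                v *= g["momentum"]
                v += d
                upd = d + g["momentum"] * v if self.nesterov else v
                p.data -= g["lr"] * upd
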