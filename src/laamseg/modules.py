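"""Backbone-tail module zoo: SPP and its atrous-attention replacements.

The family implemented here covers the full ablation grid used for the
brain-tumor segmentation study:

=========  ==============================================================
variant    composition
=========  ==============================================================
SPP        fixed-kernel max-pool pyramid (5/9/13), the YOLOv5 baseline tail
ASPP       standard atrous spatial pyramid pooling (1x1 + dilated 3x3 convs
           at rates 6/12/18 + global-pool branch, concat + 1x1 fusion)
LASPP      lightweight ASPP: 1x1 branch + depthwise-separable dilated 3x3
           branches at rates 6/12
APCM       ASPP + standard CBAM (GAP-MLP channel attention, 7x7 spatial
           attention) + residual sum
LAPCM      APCM without the residual connection
LAAM       LASPP + enhanced CBAM branch (dilated 3x3 context convolutions at
           rates 6/12, bottleneck channel attention, 1x1 spatial attention)
           + projected residual (1x1 conv + batch norm)
LLAAM      LAAM without the residual connection
=========  ==============================================================

All variants are shape-preserving in the spatial dimensions.  Attention
weights are sigmoid-gated, hence strictly inside (0, 1), and are applied
multiplicatively (channel first, then spatial — the CBAM convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import tensor as T
from .nn import (BatchNorm2d, Conv2d, ConvBnAct, Identity, MaxPool2dSame,
                 Module, Sequential)

VARIANT_TABLE = {
    # variant: (attention, residual)
    "SPP": ("none", "none"),
    "ASPP": ("none", "none"),
    "LASPP": ("none", "none"),
    "APCM": ("standard_cbam", "projected_sum"),
    "LAPCM": ("standard_cbam", "none"),
    "LLAAM": ("simplified_cbam", "none"),
    "LAAM": ("simplified_cbam", "projected_sum"),
}

_STANDARD_FAMILY = {"ASPP", "APCM", "LAPCM"}
_LIGHTWEIGHT_FAMILY = {"LASPP", "LLAAM", "LAAM"}


@dataclass
class ModuleSpec:
    """Declarative description of one tail variant.

    ``branch_width_ratio`` sets every parallel branch's output width as a
    fraction of ``in_channels``; the default 1.0 is the one-time complexity
    calibration frozen for all variants (see the profiler documentation).
    """

    variant: str
    in_channels: int = 512
    out_channels: int = 512
    dilation_rates: tuple = ()
    attention: str = ""
    residual: str = ""
    channel_reduction: int = 16
    branch_width_ratio: float = 1.0

    def __post_init__(self):
        v = self.variant
        if v not in VARIANT_TABLE:
            raise KeyError(f"unknown variant {v!r}; valid: {sorted(VARIANT_TABLE)}")
        att, res = VARIANT_TABLE[v]
        if not self.attention:
            self.attention = att
        if not self.residual:
            self.residual = res
        if (self.attention, self.residual) != (att, res):
            raise ValueError(
                f"variant {v} requires attention={att!r}, residual={res!r}; "
                f"got {self.attention!r}, {self.residual!r}")
        if not self.dilation_rates:
            if v in _STANDARD_FAMILY:
                self.dilation_rates = (6, 12, 18)
            elif v in _LIGHTWEIGHT_FAMILY:
                self.dilation_rates = (6, 12)
        if v != "SPP" and len(self.dilation_rates) < 2:
            raise ValueError("at least 2 dilation rates required")
        if self.channel_reduction > self.in_channels:
            raise ValueError("channel_reduction exceeds channel count")

    @property
    def branch_channels(self) -> int:
        return max(8, int(round(self.in_channels * self.branch_width_ratio)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleSpec":
        d = dict(d)
        if "dilation_rates" in d and d["dilation_rates"] is not None:
            d["dilation_rates"] = tuple(d["dilation_rates"])
        return cls(**d)


class DepthwiseSeparableConv(Module):
    """Per-channel dilated 3x3 (or kxk) conv + 1x1 pointwise, each BN+SiLU.

    For in=512, out=256, k=3 this holds 512*9 + 512*256 weights against
    512*256*9 for the dense conv — a ~8.7x reduction.
    """

    def __init__(self, c1, c2, k=3, d=1, norm=True, act=True):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        if d < 1:
            raise ValueError("dilation must be >= 1")
        if norm:
            self.depthwise = ConvBnAct(c1, c1, k, d=d, g=c1, act=act)
            self.pointwise = ConvBnAct(c1, c2, 1, act=act)
        else:  # unnormalized path, used by identity-initialization checks
            self.depthwise = Sequential(Conv2d(c1, c1, k, dilation=d, groups=c1, bias=False))
            self.pointwise = Sequential(Conv2d(c1, c2, 1, bias=False))
        self.in_channels, self.out_channels = c1, c2

    def forward(self, x):
        return self.pointwise(self.depthwise(x))

    def complexity(self, in_shape):
        s, e1 = self.depthwise.complexity(in_shape)
        s, e2 = self.pointwise.complexity(s)
        return s, [("dw." + n, p, f) for n, p, f in e1] + [("pw." + n, p, f) for n, p, f in e2]


class GlobalPoolBranch(Module):
    """GAP -> 1x1 conv -> broadcast back to the input's spatial extent."""

    def __init__(self, c1, c2):
        super().__init__()
        self.conv = ConvBnAct(c1, c2, 1)

    def forward(self, x):
        g = x.mean(axis=(2, 3), keepdims=True)
        g = self.conv(g)
        h, w = x.shape[2], x.shape[3]
        return g * T.Tensor(np.ones((1, 1, h, w), dtype=np.float32))

    def complexity(self, in_shape):
        c, h, w = in_shape
        out, e = self.conv.complexity((c, 1, 1))
        return (out[0], h, w), e


class SPP(Module):
    """Classic spatial pyramid pooling tail: 1x1 down, 5/9/13 max-pool pyramid, 1x1 fuse."""

    def __init__(self, c1, c2, kernels=(5, 9, 13)):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.pools = [MaxPool2dSame(k) for k in kernels]
        self.cv2 = ConvBnAct(c_ * (len(kernels) + 1), c2, 1)

    def forward(self, x):
        x = self.cv1(x)
        return self.cv2(T.concat([x] + [p(x) for p in self.pools], axis=1))

    def complexity(self, in_shape):
        s, e1 = self.cv1.complexity(in_shape)
        cat = (s[0] * (len(self.pools) + 1), s[1], s[2])
        out, e2 = self.cv2.complexity(cat)
        return out, [("cv1." + n, p, f) for n, p, f in e1] + [("cv2." + n, p, f) for n, p, f in e2]


class ASPPStandard(Module):
    """Standard atrous spatial pyramid pooling.

    Four parallel conv sub-modules (a 1x1 and a dense dilated 3x3 per rate)
    plus an image-pool branch; outputs are concatenated and fused by 1x1 conv.
    """

    def __init__(self, spec: ModuleSpec):
        super().__init__()
        c1, b = spec.in_channels, spec.branch_channels
        self.branches = [ConvBnAct(c1, b, 1)]
        self.branches += [ConvBnAct(c1, b, 3, d=r) for r in spec.dilation_rates]
        self.pool = GlobalPoolBranch(c1, b)
        self.fuse = ConvBnAct(b * (len(self.branches) + 1), spec.out_channels, 1)

    def forward(self, x):
        ys = [m(x) for m in self.branches] + [self.pool(x)]
        return self.fuse(T.concat(ys, axis=1))

    def complexity(self, in_shape):
        entries, widths = [], 0
        for i, m in enumerate(self.branches):
            s, e = m.complexity(in_shape)
            widths += s[0]
            entries += [(f"branch{i}." + n, p, f) for n, p, f in e]
        s, e = self.pool.complexity(in_shape)
        widths += s[0]
        entries += [("pool." + n, p, f) for n, p, f in e]
        out, e = self.fuse.complexity((widths, in_shape[1], in_shape[2]))
        return out, entries + [("fuse." + n, p, f) for n, p, f in e]


class ASPPLightweight(Module):
    """Lightweight ASPP: 1x1 branch + depthwise-separable dilated 3x3 branches."""

    def __init__(self, spec: ModuleSpec):
        super().__init__()
        c1, b = spec.in_channels, spec.branch_channels
        self.branches = [ConvBnAct(c1, b, 1)]
        self.branches += [DepthwiseSeparableConv(c1, b, 3, d=r) for r in spec.dilation_rates]
        self.fuse = ConvBnAct(b * len(self.branches), spec.out_channels, 1)

    def forward(self, x):
        return self.fuse(T.concat([m(x) for m in self.branches], axis=1))

    def complexity(self, in_shape):
        entries, widths = [], 0
        for i, m in enumerate(self.branches):
            s, e = m.complexity(in_shape)
            widths += s[0]
            entries += [(f"branch{i}." + n, p, f) for n, p, f in e]
        out, e = self.fuse.complexity((widths, in_shape[1], in_shape[2]))
        return out, entries + [("fuse." + n, p, f) for n, p, f in e]


# --------------------------------------------------------------------- CBAM
class ChannelAttentionStandard(Module):
    """GAP -> two fully connected layers (hidden c/r, ReLU) -> sigmoid.

    Returns one weight per channel, shape (batch, channels), all in (0, 1).
    """

    def __init__(self, c, reduction=16):
        super().__init__()
        if reduction > c:
            raise ValueError("reduction exceeds channel count")
        if c % reduction:
            raise ValueError("reduction must divide channel count")
        from .nn import Parameter, _kaiming_uniform
        h = c // reduction
        self.w1 = Parameter(_kaiming_uniform((c, h), c))
        self.b1 = Parameter(np.zeros(h))
        self.w2 = Parameter(_kaiming_uniform((h, c), h))
        self.b2 = Parameter(np.zeros(c))
        self.channels = c

    def forward(self, x):
        g = x.mean(axis=(2, 3))                      # (n, c)
        hdn = T.relu(g @ self.w1 + self.b1)
        return T.sigmoid(hdn @ self.w2 + self.b2)     # (n, c)

    def complexity(self, in_shape):
        c = self.channels
        h = self.w1.data.shape[1]
        params = sum(p.data.size for p in (self.w1, self.b1, self.w2, self.b2))
        return in_shape, [("fc", params, c * h * 2)]


class ChannelAttentionSimplified(Module):
    """GAP -> 1x1 conv bottleneck (down/up, no bias) -> sigmoid."""

    def __init__(self, c, reduction=16):
        super().__init__()
        if reduction > c:
            raise ValueError("reduction exceeds channel count")
        if c % reduction:
            raise ValueError("reduction must divide channel count")
        self.down = Conv2d(c, c // reduction, 1, bias=False)
        self.up = Conv2d(c // reduction, c, 1, bias=False)
        self.channels = c

    def forward(self, x):
        g = x.mean(axis=(2, 3), keepdims=True)        # (n, c, 1, 1)
        z = self.up(T.silu(self.down(g)))
        return T.sigmoid(z.reshape(z.shape[0], z.shape[1]))

    def complexity(self, in_shape):
        c = self.channels
        h = self.down.out_channels
        params = self.down.weight.data.size + self.up.weight.data.size
        return in_shape, [("bottleneck", params, c * h * 2)]


def _mean_max_maps(x):
    return T.concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)


class SpatialAttentionStandard(Module):
    """Channel-wise mean+max maps -> 7x7 conv -> sigmoid; shape (n, 1, h, w)."""

    def __init__(self, kernel=7):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, bias=True)

    def forward(self, x):
        return T.sigmoid(self.conv(_mean_max_maps(x)))

    def complexity(self, in_shape):
        _, h, w = in_shape
        _, e = self.conv.complexity((2, h, w))
        return in_shape, [("sa7x7." + n, p, f) for n, p, f in e]


class SpatialAttentionSimplified(Module):
    """Mean+max maps -> 1x1 conv -> sigmoid (``full_depth`` switches the input
    of the 1x1 conv to the whole channel stack instead of the pooled maps)."""

    def __init__(self, c=None, full_depth=False):
        super().__init__()
        self.full_depth = full_depth
        self.conv = Conv2d(c if full_depth else 2, 1, 1, bias=True)

    def forward(self, x):
        inp = x if self.full_depth else _mean_max_maps(x)
        return T.sigmoid(self.conv(inp))

    def complexity(self, in_shape):
        c, h, w = in_shape
        cin = c if self.full_depth else 2
        _, e = self.conv.complexity((cin, h, w))
        return in_shape, [("sa1x1." + n, p, f) for n, p, f in e]


class DilatedContext(Module):
    """The enhanced-CBAM receptive-field stage: sequential dense 3x3
    convolutions at increasing dilation rates."""

    def __init__(self, c, rates=(6, 12)):
        super().__init__()
        self.convs = [ConvBnAct(c, c, 3, d=r) for r in rates]

    def forward(self, x):
        for m in self.convs:
            x = m(x)
        return x

    def complexity(self, in_shape):
        entries = []
        for i, m in enumerate(self.convs):
            in_shape, e = m.complexity(in_shape)
            entries += [(f"ctx{i}." + n, p, f) for n, p, f in e]
        return in_shape, entries


# ------------------------------------------------------------- tail variants
class _TailBase(Module):
    def __init__(self, spec: ModuleSpec):
        super().__init__()
        self.spec = spec


class ASPPOnly(_TailBase):
    def __init__(self, spec):
        super().__init__(spec)
        self.aspp = ASPPStandard(spec)

    def forward(self, x):
        return self.aspp(x)

    def complexity(self, in_shape):
        return self.aspp.complexity(in_shape)


class LASPPOnly(_TailBase):
    def __init__(self, spec):
        super().__init__(spec)
        self.aspp = ASPPLightweight(spec)

    def forward(self, x):
        return self.aspp(x)

    def complexity(self, in_shape):
        return self.aspp.complexity(in_shape)


class APCM(_TailBase):
    """Standard ASPP, standard CBAM applied multiplicatively to its output,
    residual sum with the module input (identity when channel counts match,
    otherwise a 1x1 projection)."""

    def __init__(self, spec, with_residual=True):
        super().__init__(spec)
        self.aspp = ASPPStandard(spec)
        self.ca = ChannelAttentionStandard(spec.out_channels, spec.channel_reduction)
        self.sa = SpatialAttentionStandard()
        self.with_residual = with_residual
        if with_residual:
            if spec.in_channels == spec.out_channels:
                self.proj = Identity()
            else:
                self.proj = ConvBnAct(spec.in_channels, spec.out_channels, 1, act=False)

    def forward(self, x):
        y = self.aspp(x)
        w = self.ca(y)
        y = y * w.reshape(w.shape[0], w.shape[1], 1, 1)
        y = y * self.sa(y)
        if self.with_residual:
            y = self.proj(x) + y
        return y

    def complexity(self, in_shape):
        out, entries = self.aspp.complexity(in_shape)
        _, e = self.ca.complexity(out)
        entries += [("ca." + n, p, f) for n, p, f in e]
        _, e = self.sa.complexity(out)
        entries += [("sa." + n, p, f) for n, p, f in e]
        if self.with_residual and not isinstance(self.proj, Identity):
            _, e = self.proj.complexity(in_shape)
            entries += [("proj." + n, p, f) for n, p, f in e]
        return out, entries


class LAPCM(APCM):
    def __init__(self, spec):
        super().__init__(spec, with_residual=False)


class LAAM(_TailBase):
    """Lightweight ASPP + enhanced CBAM branch + projected residual.

    The enhanced CBAM branch first widens the receptive field with dilated 3x3
    context convolutions (rates 6 and 12), then modulates the context features
    with bottleneck channel attention and 1x1 spatial attention; the module
    input, projected by 1x1 conv + batch norm, is summed with the
    attention-enhanced features, preserving a gradient path even when all
    attention weights saturate.
    """

    def __init__(self, spec, with_residual=True):
        super().__init__(spec)
        self.aspp = ASPPLightweight(spec)
        self.ctx = DilatedContext(spec.out_channels, spec.dilation_rates)
        self.ca = ChannelAttentionSimplified(spec.out_channels, spec.channel_reduction)
        self.sa = SpatialAttentionSimplified(spec.out_channels)
        self.with_residual = with_residual
        if with_residual:
            self.proj = ConvBnAct(spec.in_channels, spec.out_channels, 1, act=False)

    def forward(self, x):
        y = self.aspp(x)
        c = self.ctx(y)
        w = self.ca(c)
        c = c * w.reshape(w.shape[0], w.shape[1], 1, 1)
        a = c * self.sa(c)
        if self.with_residual:
            a = self.proj(x) + a
        return a

    def complexity(self, in_shape):
        out, entries = self.aspp.complexity(in_shape)
        _, e = self.ctx.complexity(out)
        entries += [("ctx." + n, p, f) for n, p, f in e]
        _, e = self.ca.complexity(out)
        entries += [("ca." + n, p, f) for n, p, f in e]
        _, e = self.sa.complexity(out)
        entries += [("sa." + n, p, f) for n, p, f in e]
        if self.with_residual:
            _, e = self.proj.complexity(in_shape)
            entries += [("proj." + n, p, f) for n, p, f in e]
        return out, entries


class LLAAM(LAAM):
    def __init__(self, spec):
        super().__init__(spec, with_residual=False)


class SPPTail(_TailBase):
    def __init__(self, spec):
        super().__init__(spec)
        self.spp = SPP(spec.in_channels, spec.out_channels)

    def forward(self, x):
        return self.spp(x)

    def complexity(self, in_shape):
        return self.spp.complexity(in_shape)


_REGISTRY = {
    "SPP": SPPTail,
    "ASPP": ASPPOnly,
    "LASPP": LASPPOnly,
    "APCM": APCM,
    "LAPCM": LAPCM,
    "LLAAM": LLAAM,
    "LAAM": LAAM,
}


def build_variant(spec: ModuleSpec | str, **kwargs) -> Module:
    """Instantiate the tail module named by ``spec`` (a ModuleSpec or a
    variant name; keyword arguments feed the ModuleSpec in the latter case)."""
    if isinstance(spec, str):
        spec = ModuleSpec(spec, **kwargs)
    try:
        cls = _REGISTRY[spec.variant]
    except KeyError:
        raise KeyError(f"unknown variant {spec.variant!r}; valid: {sorted(_REGISTRY)}") from None
    return cls(spec)
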