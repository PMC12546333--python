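"""Tail-variant module zoo: shapes, attention behavior, ablation algebra."""

import numpy as np
import pytest

from laamseg import tensor as T
from laamseg.modules import (APCM, LAAM, LAPCM, LLAAM, ASPPLightweight,
                             ASPPStandard, ChannelAttentionSimplified,
                             ChannelAttentionStandard, DepthwiseSeparableConv,
                             ModuleSpec, SpatialAttentionSimplified,
                             SpatialAttentionStandard, build_variant)
from laamseg.nn import init_seed
from laamseg.profiler import profile
from laamseg.tensor import Tensor

ALL_VARIANTS = ["SPP", "ASPP", "LASPP", "APCM", "LAPCM", "LLAAM", "LAAM"]
C = 32  # small channel width keeps the forward passes fast


def _x(rng, c=C, h=16, w=16, n=1):
    return Tensor(rng.standard_normal((n, c, h, w)).astype(np.float32))


def _build(variant, c=C, **kw):
    with init_seed(0):
        m = build_variant(variant, in_channels=c, out_channels=c,
                          channel_reduction=8, **kw)
    m.eval()
    return m


# ------------------------------------------------------------------ contracts
@pytest.mark.parametrize("variant", ALL_VARIANTS)
@pytest.mark.parametrize("hw", [8, 16, 20, 32])
def test_every_variant_preserves_spatial_shape(variant, hw, rng):
    m = _build(variant)
    with T.no_grad():
        y = m(_x(rng, h=hw, w=hw))
    assert y.shape == (1, C, hw, hw)
    assert np.all(np.isfinite(y.data))


def test_variant_registry_rejects_unknown_names():
    with pytest.raises(KeyError, match="LAAM"):
        build_variant("NOPE")


def test_table_mapping_is_enforced():
    with pytest.raises(ValueError):
        ModuleSpec("LAAM", attention="none")
    spec = ModuleSpec("LLAAM", in_channels=C, out_channels=C)
    assert (spec.attention, spec.residual) == ("simplified_cbam", "none")
    assert ModuleSpec("LASPP").residual == "none"


def test_dilation_rate_validation():
    with pytest.raises(ValueError, match="dilation"):
        ModuleSpec("ASPP", dilation_rates=(6,))


# ---------------------------------------------------- depthwise separable conv
def test_depthwise_separable_parameter_economy():
    with init_seed(0):
        m = DepthwiseSeparableConv(512, 256, 3, norm=False)
    n_sep = m.param_count()
    assert n_sep == 512 * 9 + 512 * 256 == 135_680
    dense = 512 * 256 * 9
    assert n_sep / dense < 0.12


def test_depthwise_separable_identity_configuration(rng):
    # kernel 1, dilation 1, identity pointwise, no normalization: the block
    # reduces to two activations of the input
    with init_seed(0):
        m = DepthwiseSeparableConv(4, 4, k=1, d=1, norm=False, act=False)
    m.depthwise[0].weight.data[...] = 1.0
    m.pointwise[0].weight.data[...] = np.eye(4).reshape(4, 4, 1, 1)
    x = _x(rng, c=4, h=5, w=5)
    with T.no_grad():
        y = m(x)
    assert np.allclose(y.data, x.data, atol=1e-6)


def test_depthwise_separable_rejects_bad_configuration():
    with pytest.raises(ValueError):
        DepthwiseSeparableConv(8, 8, k=4)
    with pytest.raises(ValueError):
        DepthwiseSeparableConv(8, 8, k=3, d=0)


# ------------------------------------------------------------------- ASPP pair
def test_standard_aspp_pool_branch_constant_on_constant_input():
    spec = ModuleSpec("ASPP", in_channels=C, out_channels=C)
    with init_seed(0):
        m = ASPPStandard(spec)
    m.eval()
    x = Tensor(np.full((1, C, 12, 12), 3.0, dtype=np.float32))
    with T.no_grad():
        pooled = m.pool(x)
    flat = pooled.data.reshape(1, -1, 144)
    assert np.allclose(flat, flat[:, :, :1], atol=1e-6)


def test_four_conv_branch_concat_width():
    # with the two-rate configuration the concatenation carries 4 branches
    spec = ModuleSpec("ASPP", in_channels=C, out_channels=C, dilation_rates=(6, 12))
    with init_seed(0):
        m = ASPPStandard(spec)
    widths = len(m.branches) + 1  # conv branches + global pool
    assert widths == 4
    assert m.fuse.conv.in_channels == 4 * spec.branch_channels


def test_lightweight_aspp_costs_fewer_macs_than_standard():
    shape = (512, 20, 20)
    heavy = profile(ASPPStandard(ModuleSpec("ASPP", 512, 512)), shape)
    light = profile(ASPPLightweight(ModuleSpec("LASPP", 512, 512)), shape)
    assert light.macs < heavy.macs


def test_lightweight_aspp_zero_input_zero_preactivation(rng):
    spec = ModuleSpec("LASPP", in_channels=8, out_channels=8, channel_reduction=8)
    with init_seed(0):
        m = ASPPLightweight(spec)
    m.eval()
    for bn in [m.fuse.bn] + [b.bn for b in m.branches[:1]]:
        bn.bias.data[...] = 0.0
    x = Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
    with T.no_grad():
        y = m.fuse.conv(T.concat([b(x) for b in m.branches], axis=1))
    # convolution of an all-zero pre-activation stack with zero bias is zero
    assert np.allclose(np.abs(y.data).max(), 0.0, atol=1e-5)


# ------------------------------------------------------------------- attention
@pytest.mark.parametrize("cls", [ChannelAttentionStandard, ChannelAttentionSimplified])
def test_channel_attention_shape_and_range(cls, rng):
    with init_seed(0):
        m = cls(C, reduction=8)
    w = m(_x(rng, n=2))
    assert w.shape == (2, C)
    assert np.all(w.data > 0) and np.all(w.data < 1)


@pytest.mark.parametrize("cls", [ChannelAttentionStandard, ChannelAttentionSimplified])
def test_channel_attention_validates_reduction(cls):
    with pytest.raises(ValueError):
        cls(8, reduction=16)


def test_standard_channel_attention_zero_weights_give_half():
    with init_seed(0):
        m = ChannelAttentionStandard(C, reduction=8)
    for p in (m.w1, m.b1, m.w2, m.b2):
        p.data[...] = 0.0
    w = m(Tensor(np.random.default_rng(0).random((1, C, 4, 4)).astype(np.float32)))
    assert np.allclose(w.data, 0.5)


def test_standard_channel_attention_permutation_equivariance(rng):
    with init_seed(0):
        m = ChannelAttentionStandard(C, reduction=8)
    # permuting channels of both the input and the first FC layer's rows
    # permutes the pooled descriptor consistently
    x = _x(rng)
    w = m(x).data
    perm = np.random.default_rng(1).permutation(C)
    m.w1.data[...] = m.w1.data[perm]
    m.w2.data[...] = m.w2.data[:, perm]
    m.b2.data[...] = m.b2.data[perm]
    w2 = m(Tensor(x.data[:, perm])).data
    assert np.allclose(w2, w[:, perm], atol=1e-5)


def test_simplified_channel_attention_ignores_spatial_order(rng):
    with init_seed(0):
        m = ChannelAttentionSimplified(C, reduction=8)
    x = _x(rng, h=6, w=6)
    w1 = m(x).data
    shuffled = x.data.reshape(1, C, -1)
    shuffled = shuffled[:, :, np.random.default_rng(2).permutation(36)].reshape(1, C, 6, 6)
    w2 = m(Tensor(shuffled)).data
    assert np.allclose(w1, w2, atol=1e-6)


def test_simplified_channel_attention_monotone_under_nonnegative_weights(rng):
    with init_seed(0):
        m = ChannelAttentionSimplified(C, reduction=8)
    m.down.weight.data[...] = np.abs(m.down.weight.data)
    m.up.weight.data[...] = np.abs(m.up.weight.data)
    x = np.abs(rng.standard_normal((1, C, 4, 4))).astype(np.float32)
    w1 = m(Tensor(x)).data
    x2 = x.copy()
    x2[:, 3] *= 2.0
    w2 = m(Tensor(x2)).data
    assert w2[0, 3] >= w1[0, 3] - 1e-7


def test_simplified_channel_attention_parameter_economy():
    with init_seed(0):
        std = ChannelAttentionStandard(512, 16)
        simp = ChannelAttentionSimplified(512, 16)
    # the bottleneck omits the bias terms the FC pair carries
    assert simp.param_count() < std.param_count()


@pytest.mark.parametrize("cls,kwargs", [(SpatialAttentionStandard, {}),
                                        (SpatialAttentionSimplified, dict(c=C))])
def test_spatial_attention_shape_and_range(cls, kwargs, rng):
    with init_seed(0):
        m = cls(**kwargs)
    w = m(_x(rng, h=12, w=12))
    assert w.shape == (1, 1, 12, 12)
    assert np.all(w.data > 0) and np.all(w.data < 1)


def test_standard_spatial_attention_constant_input_constant_map():
    with init_seed(0):
        m = SpatialAttentionStandard()
    x = Tensor(np.full((1, C, 10, 10), 2.0, dtype=np.float32))
    w = m(x).data[0, 0]
    inner = w[3:-3, 3:-3]  # away from padding effects
    assert np.allclose(inner, inner[0, 0], atol=1e-6)


def test_single_channel_mean_and_max_coincide(rng):
    from laamseg.modules import _mean_max_maps
    x = _x(rng, c=1, h=6, w=6)
    mm = _mean_max_maps(x).data
    assert np.allclose(mm[:, 0], mm[:, 1])


def test_simplified_spatial_attention_zero_input_uniform_half():
    with init_seed(0):
        m = SpatialAttentionSimplified(C)
    m.conv.bias.data[...] = 0.0
    w = m(Tensor(np.zeros((1, C, 8, 8), dtype=np.float32)))
    assert np.allclose(w.data, 0.5)


def test_simplified_spatial_attention_cheaper_than_7x7():
    shape = (512, 20, 20)
    std = profile(SpatialAttentionStandard(), shape)
    simp = profile(SpatialAttentionSimplified(512), shape)
    assert simp.macs < std.macs


def test_attention_modulation_never_amplifies(rng):
    m = _build("LAAM")
    x = _x(rng)
    with T.no_grad():
        y = m.aspp(x)
        c = m.ctx(y)
        w = m.ca(c)
        after_ca = c * w.reshape(1, C, 1, 1)
        after_sa = after_ca * m.sa(after_ca)
    assert np.all(np.abs(after_ca.data) <= np.abs(c.data) + 1e-7)
    assert np.all(np.abs(after_sa.data) <= np.abs(after_ca.data) + 1e-7)


# ------------------------------------------------------------- ablation algebra
def _sync(dst, src):
    s = dict(src.named_parameters())
    for name, p in dst.named_parameters():
        p.data[...] = s[name].data
    sb = dict(src.named_buffers())
    for name, b in dst.named_buffers():
        b[...] = sb[name]


def test_apcm_minus_residual_equals_lapcm(rng):
    apcm, lapcm = _build("APCM"), _build("LAPCM")
    _sync(lapcm, apcm)
    x = _x(rng)
    with T.no_grad():
        full = apcm(x)
        ablated = lapcm(x)
        residual = apcm.proj(x) if not hasattr(apcm.proj, "mods") else None
    with T.no_grad():
        expected = apcm.proj(x).data + ablated.data
    assert np.abs(full.data - expected).max() == 0.0


def test_laam_minus_residual_equals_llaam(rng):
    laam, llaam = _build("LAAM"), _build("LLAAM")
    _sync(llaam, laam)
    x = _x(rng)
    with T.no_grad():
        full = laam(x).data
        expected = laam.proj(x).data + llaam(x).data  # same summation order as forward
    assert np.abs(full - expected).max() == 0.0


def test_laam_minus_attention_equals_laspp(rng):
    laam, laspp = _build("LAAM"), _build("LASPP")
    s = dict(laam.aspp.named_parameters())
    for name, p in laspp.aspp.named_parameters():
        p.data[...] = s[name].data
    sb = dict(laam.aspp.named_buffers())
    for name, b in laspp.aspp.named_buffers():
        b[...] = sb[name]
    x = _x(rng)
    with T.no_grad():
        via_laam = laam.aspp(x).data
        via_laspp = laspp(x).data
    assert np.abs(via_laam - via_laspp).max() == 0.0


# ---------------------------------------------------------------- grad plumbing
def test_laam_residual_keeps_gradient_alive_when_attention_saturates(rng):
    with init_seed(0):
        m = build_variant("LAAM", in_channels=8, out_channels=8, channel_reduction=8)
    m.eval()
    # drive the spatial attention to (numerical) zero: the multiplicative
    # path contributes no gradient, the residual projection still does
    m.sa.conv.bias.data[...] = -80.0
    x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32), requires_grad=True)
    y = m(x)
    y.sum().backward()
    assert x.grad is not None and np.abs(x.grad).max() > 0


def test_complexity_ordering_of_tail_variants():
    shape = (512, 20, 20)
    macs = {v: profile(_build(v, c=512), shape).macs
            for v in ("LASPP", "LAAM", "ASPP", "APCM")}
    assert macs["LASPP"] < macs["LAAM"] < macs["ASPP"] < macs["APCM"]


def test_seeded_construction_is_bit_identical(rng):
    a, b = _build("LAAM"), _build("LAAM")
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)
    x = _x(rng)
    with T.no_grad():
        assert np.array_equal(a(x).data, b(x).data)
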