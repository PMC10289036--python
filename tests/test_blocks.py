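"""Attention blocks, MobileNet bottlenecks and the separable-conv parameter ratio."""

import numpy as np
import pytest

from bbyolo.blocks import (BlockSpec, C3, C3Mobile, CBAM, LittleCBAM,
                           MobileNetV3Bottleneck, MSSENet, SENet,
                           separable_conv_weights, separable_param_ratio,
                           standard_conv_weights)
from bbyolo.nn import Conv2d, Tensor, seed_rng
from bbyolo.nn import functional as F

RNG = np.random.default_rng(1)


def fmap(c=16, h=8, w=8, n=2):
    return Tensor(RNG.normal(size=(n, c, h, w)).astype(np.float32))


def zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


# -- Eq-style parameter ratio ---------------------------------------------------

def test_separable_ratio_closed_form_cases():
    assert separable_param_ratio(3, 9, 3) == pytest.approx(2 / 9)
    assert separable_param_ratio(17, 64, 3) == pytest.approx(73 / 576)
    with pytest.raises(ValueError):
        separable_param_ratio(0, 4, 3)


def test_separable_ratio_equals_counted_weights():
    """Formula == ratio of actually-counted weights, for 50 random layouts."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        d_in = int(rng.integers(1, 64))
        d_out = int(rng.integers(1, 128))
        k = int(rng.choice([1, 3, 5, 7]))
        # counting oracle built from real layers
        depthwise = Conv2d(d_in, d_in, k, groups=d_in, bias=False)
        pointwise = Conv2d(d_in, d_out, 1, bias=False)
        standard = Conv2d(d_in, d_out, k, bias=False)
        counted = (depthwise.param_count() + pointwise.param_count()) \
            / standard.param_count()
        assert separable_param_ratio(d_in, d_out, k) == pytest.approx(counted)
        assert separable_conv_weights(d_in, d_out, k) == \
            depthwise.param_count() + pointwise.param_count()
        assert standard_conv_weights(d_in, d_out, k) == standard.param_count()


# -- Little-CBAM ---------------------------------------------------------------

def test_little_cbam_shape_and_zero_init_gates():
    x = fmap(12, 7, 9)
    block = LittleCBAM(12)
    assert block(x).shape == x.shape
    zero_params(block)
    out = block(x)
    assert np.allclose(out.data, 0.25 * x.data, atol=1e-6)  # two sigmoid(0) gates


def test_little_cbam_spatial_conv_is_9_49_of_cbam():
    little = LittleCBAM(32)
    big = CBAM(32)
    n_little = little.spatial_conv.param_count()
    n_big = big.spatial_conv.param_count()
    assert (n_little, n_big) == (18, 98)
    assert n_little / n_big == 9 / 49


@pytest.mark.parametrize("c", [16, 32, 64, 128, 256, 512, 1024])
def test_little_cbam_always_lighter_than_cbam(c):
    assert LittleCBAM(c).param_count() < CBAM(c).param_count()


def test_little_cbam_validation():
    with pytest.raises(ValueError):
        LittleCBAM(0)
    with pytest.raises(ValueError):
        LittleCBAM(8, k1d=4)


def test_cbam_zero_init_and_divisibility():
    x = fmap(32)
    block = CBAM(32, reduction=16)
    assert block(x).shape == x.shape
    zero_params(block)
    assert np.allclose(block(x).data, 0.25 * x.data, atol=1e-6)
    with pytest.raises(ValueError):
        CBAM(30, reduction=16)


# -- MSSENet --------------------------------------------------------------------

def test_mssenet_shape_and_zero_fc_gate():
    x = fmap(32)
    block = MSSENet(32, reduction=16)
    assert block(x).shape == x.shape
    for name in ("fc1", "fc2"):
        zero_params(getattr(block, name))
    xc = block.multi_scale(x)
    out = block(x)
    assert np.allclose(out.data, 0.5 * xc.data, atol=1e-6)  # sigmoid(0) gate
    with pytest.raises(ValueError):
        MSSENet(30, reduction=16)


def test_mssenet_max_branch_sees_spike_that_average_misses():
    """A lone bright pixel drives the max-pool branch but not plain SE."""
    seed_rng(3)
    c = 16
    block = MSSENet(c, reduction=4)
    # suppress multi-scale fusion to a single identity 3x3 pass-through
    for conv in (block.conv5, block.conv7):
        conv.weight.data = np.zeros_like(conv.weight.data)
    w = np.zeros_like(block.conv3.weight.data)
    for i in range(c):
        w[i, i, 1, 1] = 1.0
    block.conv3.weight.data = w

    sen = SENet(c, reduction=4, act="mish")
    sen.fc1.weight.data = block.fc1.weight.data.copy()
    sen.fc1.bias.data = block.fc1.bias.data.copy()
    sen.fc2.weight.data = block.fc2.weight.data.copy()
    sen.fc2.bias.data = block.fc2.bias.data.copy()

    spike = np.zeros((1, c, 32, 32), np.float32)
    spike[0, 3, 5, 7] = 50.0  # huge local response, negligible average
    x = Tensor(spike)
    gate_ms = block.gate(block.multi_scale(x)).data.ravel()
    gate_se = sen.gate(x).data.ravel()
    assert not np.allclose(gate_ms, gate_se, atol=1e-3)

    # with the max branch removed, the identity-conv MSSENet degenerates to SENet
    xc = block.multi_scale(x)
    n, ch = xc.shape[:2]
    avg = F.global_avg_pool(xc).reshape(n, ch)
    gate_avg_only = block.fc2(block.fc1(avg).mish()).sigmoid().data.ravel()
    assert np.allclose(gate_avg_only, gate_se, atol=1e-6)


# -- MobileNetV3 bottleneck and C3Mobile ---------------------------------------

def test_bottleneck_shapes_and_residual():
    x = fmap(16, 9, 9)
    b1 = MobileNetV3Bottleneck(BlockSpec(16, 16, 32))
    assert b1.residual and b1(x).shape == x.shape
    b2 = MobileNetV3Bottleneck(BlockSpec(16, 24, 32, stride=2))
    out = b2(x)
    assert out.shape == (2, 24, 5, 5)  # ceil(9/2)
    with pytest.raises(ValueError):
        BlockSpec(16, 16, 32, stride=3)


def test_bottleneck_attention_cost_is_exactly_little_cbam():
    spec_on = BlockSpec(16, 24, 48, use_little_cbam=True)
    spec_off = BlockSpec(16, 24, 48, use_little_cbam=False)
    seed_rng(0)
    with_attn = MobileNetV3Bottleneck(spec_on).param_count()
    seed_rng(0)
    without = MobileNetV3Bottleneck(spec_off).param_count()
    assert with_attn - without == LittleCBAM(48).param_count()


def test_bottleneck_depthwise_matches_separable_ratio():
    spec = BlockSpec(16, 16, 48, kernel=3, use_little_cbam=False)
    block = MobileNetV3Bottleneck(spec)
    dw = block.depthwise.conv.param_count()
    pw = block.project.conv.param_count()
    standard = standard_conv_weights(48, 16, 3)
    assert (dw + pw) / standard == pytest.approx(separable_param_ratio(48, 16, 3))


def test_c3mobile_shapes_and_lightness():
    x = fmap(32, 8, 8)
    empty = C3Mobile(32, 48, n=0)
    assert empty(x).shape == (2, 48, 8, 8)
    assert len(empty.m) == 0
    deep = C3Mobile(32, 48, n=2)
    assert deep(x).shape == (2, 48, 8, 8)
    # lighter than the CSP block it replaces, at equal dims and depth
    assert C3Mobile(64, 64, n=3).param_count() < C3(64, 64, n=3).param_count()


def test_attention_outputs_finite_and_gates_in_unit_interval():
    x = fmap(16)
    for block in (LittleCBAM(16), CBAM(16, 8), MSSENet(16, 8), SENet(16, 8)):
        out = block(x)
        assert np.all(np.isfinite(out.data))
    lc = LittleCBAM(16)
    g1 = lc.channel_gate(x).data
    g2 = lc.spatial_gate(x).data
    assert np.all((g1 > 0) & (g1 < 1)) and np.all((g2 > 0) & (g2 < 1))
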