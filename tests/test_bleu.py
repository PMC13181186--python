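"""Bidirectional lesion-enhancement step: thresholds, oracles, properties."""

import numpy as np
import pytest
from scipy import signal

from mbleformer import (BLEU, BLEUConfig, ConfigError, DimensionError,
                        FeatureMap, FusionPair, bleu_fuse, bleu_step,
                        focus_map)
from mbleformer.nn import Tensor


def _fm(rng, c, h, w, stride, scale=1.0):
    return FeatureMap(
        Tensor(rng.normal(0, scale, (1, c, h, w)).astype(np.float32)), stride)


@pytest.fixture
def step(rng):
    return BLEU(c1=4, c2=8, rng=rng)


# -- alignment --------------------------------------------------------------


def test_align_resolution_upsamples_and_projects(step, rng):
    x2 = _fm(rng, 8, 7, 7, 16)
    target = _fm(rng, 4, 14, 14, 8)
    out = step.align_resolution(x2, target)
    assert out.shape == (1, 4, 14, 14)


def test_align_resolution_constant_preserved(rng):
    step = BLEU(c1=1, c2=1, rng=rng)
    step.proj.weight.data[:] = 1.0
    step.proj.bias.data[:] = 0.0
    x2 = FeatureMap(Tensor(np.full((1, 1, 5, 5), 2.0, dtype=np.float32)), 16)
    target = FeatureMap(Tensor(np.zeros((1, 1, 10, 10), dtype=np.float32)), 8)
    out = step.align_resolution(x2, target)
    assert np.allclose(out.data, 2.0, atol=1e-6)


def test_align_resolution_rejects_non_double_target(step, rng):
    x2 = _fm(rng, 8, 4, 4, 16)
    target = _fm(rng, 4, 12, 12, 8)     # 3x, not 2x
    with pytest.raises(DimensionError):
        step.align_resolution(x2, target)


# -- forward enhancement ----------------------------------------------------


def test_initial_importance_matches_conv_add_oracle(step, rng):
    x1 = rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32)
    x2u = rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32)
    out = step.initial_importance(Tensor(x1), Tensor(x2u)).data
    expected = np.zeros((4, 6, 6))
    for co in range(4):
        for ci in range(4):
            expected[co] += signal.correlate2d(
                x1[0, ci], step.conv_a.weight.data[co, ci], mode="same")
            expected[co] += signal.correlate2d(
                x2u[0, ci], step.conv_b.weight.data[co, ci], mode="same")
        expected[co] += step.conv_a.bias.data[co] + step.conv_b.bias.data[co]
    assert np.allclose(out[0], expected, atol=1e-6)


def test_initial_importance_zero_inputs_zero_bias(step):
    step.conv_a.bias.data[:] = 0.0
    step.conv_b.bias.data[:] = 0.0
    z = Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32))
    assert np.allclose(step.initial_importance(z, z).data, 0.0)


def test_initial_importance_rejects_shape_mismatch(step, rng):
    a = Tensor(rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32))
    b = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
    with pytest.raises(DimensionError):
        step.initial_importance(a, b)


def _logit(w):
    return float(np.log(w / (1.0 - w)))


def test_focus_map_threshold_grid_exact():
    """Grid {0, b-eps, b, (a+b)/2, a, a+eps, 1} maps to
    {0, 0, pass, pass, 1, 1, 1} exactly under the mid-band pass rule."""
    alpha, beta, eps = 0.6, 0.1, 1e-3

    def feat_for(target, at_least=None, below=None):
        """Pre-activation whose float32 sigmoid realises the grid point on
        the intended side of the threshold (0.6/0.1 are not dyadic, so the
        boundary cases are nudged to the first representable value)."""
        f = np.float32(_logit(target))
        sig = lambda v: np.float32(1.0) / (np.float32(1.0) + np.exp(-v))
        while at_least is not None and sig(f) < at_least:
            f = np.nextafter(f, np.float32(np.inf))
        while below is not None and sig(f) >= below:
            f = np.nextafter(f, np.float32(-np.inf))
        return f

    feats = np.array([
        -40.0,                                   # w ~ 0
        feat_for(beta - eps, below=beta),        # just under beta
        feat_for(beta, at_least=beta),           # w = beta (>= side)
        feat_for((alpha + beta) / 2),            # mid-band
        feat_for(alpha, at_least=alpha),         # w = alpha (>= side)
        feat_for(alpha + eps, at_least=alpha),   # just over alpha
        40.0,                                    # w ~ 1
    ], dtype=np.float32)
    f = Tensor(feats)
    w = 1.0 / (1.0 + np.exp(-feats))        # realised float32 sigmoid values
    out = focus_map(f, alpha, beta).data
    expected = np.where(w >= alpha, 1.0, np.where(w < beta, 0.0, w))
    assert np.array_equal(out, expected.astype(np.float32))
    assert out[0] == 0.0 and out[1] == 0.0
    assert out[4] == 1.0 and out[5] == 1.0 and out[6] == 1.0
    # mid-band entries pass the soft sigmoid weight through unchanged
    assert out[2] == w[2].astype(np.float32)
    assert out[3] == w[3].astype(np.float32)


def test_focus_map_zero_midband_variant():
    f = Tensor(np.array([_logit(0.3)], dtype=np.float32))
    assert focus_map(f, 0.6, 0.1, midband="zero").data[0] == 0.0


def test_focus_map_rejects_inverted_thresholds():
    with pytest.raises(ConfigError):
        focus_map(Tensor(np.zeros(1, dtype=np.float32)), 0.1, 0.6)


def test_focus_map_straight_through_gradient():
    f = Tensor(np.array([_logit(0.7), _logit(0.05), _logit(0.3)],
                        dtype=np.float32), requires_grad=True)
    focus_map(f, 0.6, 0.1).sum().backward()
    # gradient is the sigmoid derivative everywhere, including hard regions
    s = 1.0 / (1.0 + np.exp(-f.data))
    assert np.allclose(f.grad, s * (1 - s), atol=1e-6)


# -- reverse enhancement ----------------------------------------------------


def test_reverse_map_neutral_at_half(step, rng):
    for conv in (step.conv_c, step.conv_d):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    x = Tensor(rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32))
    assert np.allclose(step.reverse_map(x, x).data, 1.0, atol=1e-6)


def test_reverse_map_range_and_saturation(step, rng):
    x = Tensor(rng.normal(0, 1, (1, 4, 6, 6)).astype(np.float32))
    r = step.reverse_map(x, x).data
    assert np.all(r > 0) and np.all(r < 2)
    for conv in (step.conv_c, step.conv_d):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 25.0     # saturated lesion evidence
    assert np.all(step.reverse_map(x, x).data < 1e-6)


# -- fusion -----------------------------------------------------------------


def test_bleu_fuse_algebra(rng):
    feature = Tensor(rng.normal(0, 1, (1, 2, 4, 4)).astype(np.float32))
    zero = Tensor(np.zeros_like(feature.data))
    one = Tensor(np.ones_like(feature.data))
    assert np.allclose(bleu_fuse(feature, zero, one, 1.2).data, feature.data)
    assert np.allclose(bleu_fuse(feature, one, one, 0.0).data, feature.data)
    assert np.allclose(
        bleu_fuse(Tensor(np.ones(1, dtype=np.float32)), Tensor(np.ones(1)),
                  Tensor(np.ones(1)), 1.2).data, 2.2)


def test_fuse_monotone_in_focus_and_reverse(rng):
    feature = Tensor(np.abs(rng.normal(0, 1, (1, 2, 4, 4))).astype(np.float32))
    lo = Tensor(np.full_like(feature.data, 0.2))
    hi = Tensor(np.full_like(feature.data, 0.8))
    one = Tensor(np.ones_like(feature.data))
    assert np.all(bleu_fuse(feature, hi, one, 1.2).data
                  >= bleu_fuse(feature, lo, one, 1.2).data)
    assert np.all(bleu_fuse(feature, one, hi, 1.2).data
                  >= bleu_fuse(feature, one, lo, 1.2).data)


def test_residual_guarantee_where_focus_zero(rng):
    feature = Tensor(rng.normal(0, 1, (1, 2, 4, 4)).astype(np.float32))
    reverse = Tensor(rng.uniform(0, 2, (1, 2, 4, 4)).astype(np.float32))
    focus = Tensor((rng.uniform(0, 1, (1, 2, 4, 4)) > 0.5).astype(np.float32))
    out = bleu_fuse(feature, focus, reverse, 1.2).data
    mask = focus.data == 0
    assert np.array_equal(out[mask], feature.data[mask])


# -- whole step -------------------------------------------------------------


def test_bleu_step_stride_and_channels(rng):
    pair = FusionPair(x1=_fm(rng, 4, 14, 14, 8), x2=_fm(rng, 8, 7, 7, 16))
    out = bleu_step(pair, seed=3)
    assert out.stride == 8
    assert out.shape == (1, 4, 14, 14)


def test_bleu_step_deterministic_and_finite(rng):
    x1 = _fm(rng, 4, 8, 8, 8, scale=10.0)
    x2 = _fm(rng, 8, 4, 4, 16, scale=10.0)
    a = bleu_step(FusionPair(x1, x2), seed=5).data.data
    b = bleu_step(FusionPair(x1, x2), seed=5).data.data
    assert np.array_equal(a, b)
    assert np.all(np.isfinite(a))


def test_fusion_pair_validates_dims(rng):
    with pytest.raises(DimensionError):
        FusionPair(x1=_fm(rng, 4, 12, 12, 8), x2=_fm(rng, 8, 5, 5, 16))


def test_bleu_config_validation():
    with pytest.raises(ConfigError):
        BLEUConfig(alpha=0.3, beta=0.5).validate()
    with pytest.raises(ConfigError):
        BLEUConfig(gamma=-1.0).validate()
    BLEUConfig().validate()   # defaults are the tuned triple


def test_bleu_step_gradients_reach_inputs(rng):
    x1 = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32),
                requires_grad=True)
    x2 = Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32),
                requires_grad=True)
    pair = FusionPair(FeatureMap(x1, 8), FeatureMap(x2, 16))
    out = BLEU(4, 8, rng=np.random.default_rng(0))(pair)
    out.data.sum().backward()
    for t in (x1, x2):
        assert t.grad is not None
        assert np.all(np.isfinite(t.grad))
        assert np.abs(t.grad).max() > 0
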