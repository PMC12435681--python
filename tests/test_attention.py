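"""CBAM: hand-set weight oracles, bounds, shape preservation and the
channel-first application order."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2light.attention import (CBAMConfig, CBAMWeights, append_cbam,
                                 apply_cbam, channel_attention,
                                 spatial_attention)
from her2light.nn import ModelBuilder
from her2light.nn.layers import Identity


def sigmoid(x):
    return 1 / (1 + np.exp(-x))


@pytest.fixture
def small_weights():
    """Hand-set weights for a 2-channel map, reduction ratio 2, 3x3 spatial."""
    return CBAMWeights(
        w1=np.array([[0.5], [-0.25]]),
        b1=np.array([0.1]),
        w2=np.array([[1.0, -2.0]]),
        b2=np.array([0.05, -0.05]),
        spatial_kernel=np.arange(-4, 5).reshape(3, 3, 1) / 10.0 * np.ones((1, 1, 2)),
        spatial_bias=0.02,
    )


def test_config_validation():
    with pytest.raises(ValueError):
        CBAMConfig(spatial_kernel=4)
    with pytest.raises(ValueError):
        CBAMConfig(reduction_ratio=0)
    with pytest.raises(ValueError):
        CBAMConfig(reduction_ratio=32).hidden_units(16)
    assert CBAMConfig(reduction_ratio=16).hidden_units(64) == 4


def test_channel_attention_constant_map_doubles_mlp_logit(small_weights):
    # constant map: avg pool == max pool, so the pre-sigmoid logit is twice
    # the shared-MLP output of the constant channel vector
    f = np.ones((4, 4, 2)) * np.array([2.0, -1.0])
    w = small_weights
    vec = np.array([2.0, -1.0])
    h = np.maximum(vec @ w.w1 + w.b1, 0)
    logit = 2 * (h @ w.w2 + w.b2)
    np.testing.assert_allclose(channel_attention(f, w), sigmoid(logit), rtol=1e-12)


def test_channel_attention_hand_oracle_2x2x2(small_weights):
    f = np.array([[[1.0, 0.0], [2.0, -1.0]],
                  [[0.5, 3.0], [-2.0, 1.0]]])
    w = small_weights

    def mlp(v):
        return np.maximum(v @ w.w1 + w.b1, 0) @ w.w2 + w.b2

    avg = np.array([f[..., c].mean() for c in range(2)])
    mx = np.array([f[..., c].max() for c in range(2)])
    expected = sigmoid(mlp(avg) + mlp(mx))
    got = channel_attention(f, w, CBAMConfig(reduction_ratio=2, spatial_kernel=3))
    np.testing.assert_allclose(got, expected, rtol=1e-12)
    assert got.shape == (2,)
    assert np.all((got > 0) & (got < 1))


def test_spatial_attention_bruteforce_conv_oracle(small_weights):
    rng = np.random.default_rng(0)
    f = rng.random((3, 3, 2))
    w = small_weights
    stack = np.stack([f.mean(-1), f.max(-1)], axis=-1)
    padded = np.pad(stack, ((1, 1), (1, 1), (0, 0)))
    expected = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            expected[i, j] = sigmoid(
                (padded[i : i + 3, j : j + 3] * w.spatial_kernel).sum() + w.spatial_bias)
    got = spatial_attention(f, w)
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_spatial_attention_channel_constant_symmetry(small_weights):
    # channel-constant input: channel-avg equals channel-max map
    f = np.tile(np.arange(9.0).reshape(3, 3, 1), (1, 1, 2))
    w = small_weights
    one_channel = CBAMWeights(w.w1, w.b1, w.w2, w.b2,
                              w.spatial_kernel, w.spatial_bias)
    got = spatial_attention(f, one_channel)
    # equivalent map built from doubling either stacked channel
    stack = np.stack([f[..., 0], f[..., 0]], axis=-1)
    padded = np.pad(stack, ((1, 1), (1, 1), (0, 0)))
    expected = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            expected[i, j] = sigmoid(
                (padded[i : i + 3, j : j + 3] * w.spatial_kernel).sum() + w.spatial_bias)
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_apply_cbam_composes_channel_then_spatial(small_weights):
    rng = np.random.default_rng(1)
    f = rng.standard_normal((4, 4, 8))
    cfg = CBAMConfig(reduction_ratio=2, spatial_kernel=3)
    w = CBAMWeights.initialize(8, cfg, rng=np.random.default_rng(2))
    ca = channel_attention(f, w)
    f_ca = f * ca
    expected = f_ca * spatial_attention(f_ca, w)[..., None]
    np.testing.assert_allclose(apply_cbam(f, w, cfg), expected, rtol=1e-12)
    # order sensitivity: spatial-then-channel differs on generic input
    sa_first = f * spatial_attention(f, w)[..., None]
    other = sa_first * channel_attention(sa_first, w)
    assert not np.allclose(apply_cbam(f, w, cfg), other)


def test_apply_cbam_zero_input_gives_zero_output(small_weights):
    out = apply_cbam(np.zeros((5, 5, 2)), small_weights)
    np.testing.assert_array_equal(out, 0)


def test_saturated_attention_recovers_identity():
    # huge positive MLP/conv biases drive both sigmoids to ~1
    w = CBAMWeights(w1=np.zeros((2, 1)), b1=np.array([0.0]),
                    w2=np.zeros((1, 2)), b2=np.array([50.0, 50.0]),
                    spatial_kernel=np.zeros((3, 3, 2)), spatial_bias=50.0)
    rng = np.random.default_rng(3)
    f = rng.random((4, 4, 2))
    np.testing.assert_allclose(apply_cbam(f, w), f, rtol=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(h=st.integers(1, 6), wdt=st.integers(1, 6), c=st.integers(1, 8),
       seed=st.integers(0, 100))
def test_cbam_shape_and_boundedness_properties(h, wdt, c, seed):
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((h, wdt, c))
    cfg = CBAMConfig(reduction_ratio=min(2, c), spatial_kernel=3)
    w = CBAMWeights.initialize(c, cfg, rng)
    out = apply_cbam(f, w, cfg)
    assert out.shape == f.shape
    assert np.all(np.abs(out) <= np.abs(f) + 1e-12)  # attention weights < 1
    ca = channel_attention(f, w, cfg)
    assert np.all((ca > 0) & (ca < 1))
    sa = spatial_attention(f, w, cfg)
    assert sa.shape == (h, wdt)
    assert np.all((sa > 0) & (sa < 1))


def test_graph_cbam_matches_functional_ops():
    """The trainable graph implementation equals the numpy functional path."""
    cfg = CBAMConfig(reduction_ratio=4, spatial_kernel=3)
    rng = np.random.default_rng(4)
    b = ModelBuilder("in")
    b.add("id", Identity())
    out = append_cbam(b, "id", 8, cfg, rng)
    model = b.build(out)
    # lift the graph weights into a CBAMWeights for the functional oracle
    layers = dict(model.weighted_layers())
    d1, d2 = layers["cbam_gap_h"], layers["cbam_gap_o"]
    conv = layers["cbam_sa_conv"]
    w = CBAMWeights(d1.w.value, d1.b.value, d2.w.value, d2.b.value,
                    conv.w.value[:, :, :, 0], float(conv.b.value[0]))
    f = np.random.default_rng(5).standard_normal((6, 6, 8)).astype(np.float32)
    got = model.forward(f[None]).outputs[model.output_name][0]
    expected = apply_cbam(f, w, cfg)
    np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-6)


def test_param_count_formula():
    cfg = CBAMConfig(reduction_ratio=16, spatial_kernel=7, mlp_bias=True)
    # 64 channels: shared MLP 64->4->64 with biases + 7x7x2 conv with bias
    assert cfg.param_count(64) == (64 * 4 + 4) + (4 * 64 + 64) + (49 * 2 + 1)
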