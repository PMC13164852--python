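"""LRPNet architecture conformance and estimator behaviour."""

import numpy as np
import pytest
from sklearn.base import clone

from lrpnet import nn
from lrpnet.model import (
    LRPNet,
    LRPNetClassifier,
    LRPNetConfig,
    PoolFormerBlock,
    ResidualBlock,
    count_parameters,
)

# Layer-by-layer closed-form count for the default 5-class model,
# frozen as a regression constant:
#   embed 1->16 (1x1 + bias)                       32
#   poolformer(16): 2 BN (64) + MLP 16->64->16   2128 + pools 0
#   residual c_in->c_out: dw 9*c_in + pw c_in*c_out + BN 2*c_out
#     + ECA k(c_out) + projection (c_in*c_out + 2*c_out) when c_in != c_out
#   head 128*5 + 5
FULL_5CLASS_PARAM_COUNT = 65_816


class TestShapeChain:
    def test_shape_probe_matches_layer_table(self):
        net = LRPNet(LRPNetConfig(num_classes=5))
        net.set_training(False)
        trace = net.forward_trace(np.zeros((1, 1, 30, 30), dtype=np.float32))
        assert trace == [
            ("input", (1, 30, 30)),
            ("pointwise_embed", (16, 30, 30)),
            ("poolformer", (16, 30, 30)),
            ("residual_1", (32, 30, 30)),
            ("residual_2", (64, 30, 30)),
            ("residual_3", (96, 30, 30)),
            ("residual_4", (128, 30, 30)),
            ("residual_5", (128, 30, 30)),
            ("gap", (128, 1, 1)),
            ("softmax", (5,)),
        ]

    def test_softmax_output_normalized(self):
        net = LRPNet(LRPNetConfig(num_classes=5))
        net.set_training(False)
        p = net.predict_proba(np.random.default_rng(0).normal(size=(7, 1, 30, 30)))
        assert p.shape == (7, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0) and np.all(p < 1)

    def test_wrong_input_shape_rejected(self):
        net = LRPNet(LRPNetConfig(num_classes=2))
        with pytest.raises(ValueError, match="expected input"):
            net.forward(np.zeros((2, 1, 28, 28)))

    def test_ablation_variants_share_one_code_path(self):
        x = np.random.default_rng(1).normal(size=(2, 1, 30, 30)).astype(np.float32)
        for pf in (True, False):
            for eca in (True, False):
                net = LRPNet(
                    LRPNetConfig(num_classes=2, use_poolformer=pf, use_eca=eca)
                )
                net.set_training(False)
                p = net.predict_proba(x)
                np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestParameterCount:
    def test_full_model_count_frozen_and_below_one_million(self):
        n = count_parameters(LRPNetConfig(num_classes=5))
        assert n == FULL_5CLASS_PARAM_COUNT
        assert n < 1_000_000

    def test_module_monotonicity(self):
        full = count_parameters(LRPNetConfig(num_classes=5))
        no_eca = count_parameters(LRPNetConfig(num_classes=5, use_eca=False))
        neither = count_parameters(
            LRPNetConfig(num_classes=5, use_eca=False, use_poolformer=False)
        )
        assert full > no_eca > neither

    def test_eca_adds_at_most_kernel_parameters_per_block(self):
        base = count_parameters(LRPNetConfig(num_classes=5, use_eca=False))
        with_eca = count_parameters(LRPNetConfig(num_classes=5, eca_kernel=3))
        assert with_eca - base <= 5 * 3


class TestBlocks:
    def test_pointwise_embed_is_local(self):
        # output at a pixel depends only on the input at that pixel
        rng = np.random.default_rng(0)
        conv = nn.Conv1x1(1, 16, rng, dtype=np.float64)
        x = rng.normal(size=(1, 1, 30, 30))
        y1 = conv.forward(x)
        x2 = x.copy()
        x2[0, 0, 10, 20] += 1.0
        y2 = conv.forward(x2)
        diff = np.abs(y2 - y1).sum(axis=(0, 1))
        assert diff[10, 20] > 0
        diff[10, 20] = 0
        assert np.all(diff == 0)

    def test_zero_input_zero_bias_embed_gives_zero(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv1x1(1, 16, rng, dtype=np.float64)
        conv.bias.value[...] = 0.0
        y = conv.forward(np.zeros((2, 1, 30, 30)))
        np.testing.assert_array_equal(y, 0.0)

    def test_token_mixer_zero_on_constant_input(self):
        rng = np.random.default_rng(0)
        blk = PoolFormerBlock(4, rng, dtype=np.float64)
        x = np.full((2, 4, 6, 6), 3.7)
        np.testing.assert_allclose(blk.mix_tokens(x), 0.0, atol=1e-12)

    def test_token_mixer_impulse_response_matches_hand_convolution(self):
        # 5x5 grid, 3x3 mean pool with border renormalization: the mixer
        # response to a centre impulse is the pooling footprint minus the
        # impulse itself
        blk = PoolFormerBlock(1, np.random.default_rng(0), pool_size=3,
                              dtype=np.float64)
        x = np.zeros((1, 1, 5, 5))
        x[0, 0, 2, 2] = 1.0
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0 / 9.0
        expected[2, 2] -= 1.0
        np.testing.assert_allclose(blk.mix_tokens(x)[0, 0], expected, atol=1e-12)

    def test_eca_zero_weights_halve_the_input(self):
        rng = np.random.default_rng(0)
        gate = nn.ECAGate(8, rng, dtype=np.float64)
        gate.weight.value[...] = 0.0
        x = rng.normal(size=(2, 8, 4, 4))
        np.testing.assert_allclose(gate.forward(x), x / 2.0, atol=1e-12)

    def test_residual_with_zero_main_path_reduces_to_relu_shortcut(self):
        rng = np.random.default_rng(0)
        blk = ResidualBlock(6, 6, rng, use_eca=False, dtype=np.float64)
        blk.dw.weight.value[...] = 0.0
        blk.pw.weight.value[...] = 0.0
        blk.set_training(False)
        x = rng.normal(size=(2, 6, 5, 5))
        # identity shortcut, main path collapses to BN(0) = beta = 0
        np.testing.assert_allclose(blk.forward(x), np.maximum(x, 0), atol=1e-12)

    def test_final_block_uses_identity_shortcut(self):
        net = LRPNet(LRPNetConfig(num_classes=5))
        assert net.blocks[-1].proj is None
        assert all(b.proj is not None for b in net.blocks[:-1])

    def test_even_pool_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            LRPNetConfig(num_classes=5, pool_size=4)


class TestClassifierEstimator:
    def test_sklearn_params_roundtrip_and_clone(self):
        clf = LRPNetClassifier(use_eca=False, epochs=3, random_state=1)
        params = clf.get_params()
        assert params["use_eca"] is False and params["epochs"] == 3
        clone(clf)  # must not raise
        clf.set_params(epochs=5)
        assert clf.epochs == 5

    def test_fit_predict_on_separable_toy_data(self):
        # two classes of windows with clearly different spatial frequency
        rng = np.random.default_rng(0)
        t = np.arange(900) / 30.0
        X, y = [], []
        for i in range(40):
            f = 0.1 if i % 2 == 0 else 0.8
            x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x += rng.normal(0, 0.1, size=900)
            X.append((x - x.min()) / (x.max() - x.min()))
            y.append(i % 2)
        X, y = np.array(X), np.array(y)
        clf = LRPNetClassifier(epochs=8, batch_size=10, learning_rate=3e-3,
                               random_state=0)
        clf.fit(X, y)
        assert clf.classes_.tolist() == [0, 1]
        assert clf.n_features_in_ == 900
        assert (clf.predict(X) == y).mean() > 0.95
        proba = clf.predict_proba(X[:5])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_fit_is_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 900))
        y = np.repeat([0, 1], 10)
        a = LRPNetClassifier(epochs=2, batch_size=10, random_state=7).fit(X, y)
        b = LRPNetClassifier(epochs=2, batch_size=10, random_state=7).fit(X, y)
        assert a.loss_curve_ == b.loss_curve_
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_zero_epochs_returns_initialized_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 900))
        y = np.repeat([0, 1], 5)
        clf = LRPNetClassifier(epochs=0, random_state=0).fit(X, y)
        assert clf.loss_curve_ == []
        assert clf.predict(X).shape == (10,)

    def test_single_class_rejected(self):
        X = np.zeros((5, 900))
        with pytest.raises(ValueError, match="two classes"):
            LRPNetClassifier(epochs=1).fit(X, np.zeros(5))
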