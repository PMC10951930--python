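"""Squeeze-excitation, gated attention, aggregation, classifier, checkpoints."""

from __future__ import annotations

import math
import time

import numpy as np
import pytest

from sirmil.milmodel import (
    AttentionParams,
    MILModel,
    classify_bag,
    gated_attention,
    load_checkpoint,
    max_pool_aggregate,
    save_checkpoint,
    squeeze_excite,
)
from sirmil.nn import sigmoid
from sirmil.training import bag_bce


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class TestSqueezeExcite:
    def test_zero_input_stays_zero(self, rng):
        W1 = rng.normal(size=(2, 4))
        W2 = rng.normal(size=(4, 2))
        out = squeeze_excite(np.zeros((4, 3, 3)), W1, W2)
        assert (out == 0).all()

    def test_zero_weights_halve_input(self, rng):
        x = rng.normal(size=(4, 3, 3))
        out = squeeze_excite(x, np.zeros((2, 4)), np.zeros((4, 2)))
        np.testing.assert_allclose(out, 0.5 * x)

    def test_matches_scalar_hand_evaluation(self):
        """C=2 with 1x1 spatial extent: evaluate gap/relu/logistic by hand."""
        x = np.array([[[2.0]], [[-1.0]]])          # gap = (2, -1)
        W1 = np.array([[0.5, 1.0]])                # hidden = relu(0.5*2 + 1*(-1)) = 0
        W2 = np.array([[2.0], [-3.0]])
        g1, g2 = _logistic(0.0), _logistic(0.0)    # relu output is 0 -> gates 0.5
        out = squeeze_excite(x, W1, W2)
        np.testing.assert_allclose(out[:, 0, 0], [2.0 * g1, -1.0 * g2])
        # a second instance with a non-zero hidden unit
        x2 = np.array([[[4.0]], [[1.0]]])          # gap = (4, 1); hidden = relu(3) = 3
        out2 = squeeze_excite(x2, W1, W2)
        np.testing.assert_allclose(
            out2[:, 0, 0], [4.0 * _logistic(6.0), 1.0 * _logistic(-9.0)]
        )

    def test_gates_near_one_give_identity(self):
        """Saturated positive gates leave the feature map unchanged."""
        x = np.abs(np.random.default_rng(3).normal(size=(2, 4, 4))) + 0.5
        W1 = np.full((1, 2), 10.0)
        W2 = np.full((2, 1), 10.0)
        np.testing.assert_allclose(squeeze_excite(x, W1, W2), x, atol=1e-6, rtol=0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            squeeze_excite(np.zeros((4, 2, 2)), rng.normal(size=(2, 3)), rng.normal(size=(3, 2)))


class TestGatedAttention:
    def test_single_tile_gets_all_attention(self, rng):
        h = rng.normal(size=(1, 5))
        params = AttentionParams(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)), rng.normal(size=3))
        a, z = gated_attention(h, params)
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(z, h[0])

    def test_identical_tiles_get_uniform_attention(self, rng):
        h = np.tile(rng.normal(size=(1, 4)), (6, 1))
        params = AttentionParams(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)), rng.normal(size=3))
        a, z = gated_attention(h, params)
        np.testing.assert_allclose(a, np.full(6, 1 / 6))
        np.testing.assert_allclose(z, h[0])

    def test_matches_scalar_hand_evaluation(self):
        """k=2, d=2, L=2: tanh/logistic/softmax chain evaluated element-wise."""
        H = np.array([[1.0, -0.5], [0.2, 0.8]])
        V = np.array([[0.3, -0.2], [0.5, 0.1]])
        U = np.array([[-0.4, 0.6], [0.2, 0.3]])
        w = np.array([1.5, -0.7])
        scores = []
        for h in H:
            t = [math.tanh(V[0] @ h), math.tanh(V[1] @ h)]
            s = [_logistic(U[0] @ h), _logistic(U[1] @ h)]
            scores.append(w[0] * t[0] * s[0] + w[1] * t[1] * s[1])
        e = [math.exp(v - max(scores)) for v in scores]
        a_exp = np.array(e) / sum(e)
        z_exp = a_exp[0] * H[0] + a_exp[1] * H[1]
        a, z = gated_attention(H, AttentionParams(V, U, w))
        np.testing.assert_allclose(a, a_exp, rtol=1e-12)
        np.testing.assert_allclose(z, z_exp, rtol=1e-12)

    def test_attention_is_probability_vector(self, rng):
        H = rng.normal(size=(9, 6))
        params = AttentionParams(rng.normal(size=(4, 6)), rng.normal(size=(4, 6)), rng.normal(size=4))
        a, _ = gated_attention(H, params)
        assert (a >= 0).all()
        assert a.sum() == pytest.approx(1.0, abs=1e-6)

    def test_non_finite_features_rejected(self, rng):
        params = AttentionParams(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)), rng.normal(size=2))
        with pytest.raises(ValueError):
            gated_attention(np.array([[1.0, np.nan, 0.0]]), params)


class TestAggregationAndClassifier:
    def test_max_pool_examples(self):
        assert max_pool_aggregate([0.2, 0.9, 0.4]) == 0.9
        assert max_pool_aggregate([0.37]) == 0.37
        assert max_pool_aggregate([0.4, 0.2, 0.9]) == max_pool_aggregate([0.9, 0.4, 0.2])
        with pytest.raises(ValueError):
            max_pool_aggregate([])

    def test_classifier_hand_values(self):
        z = np.array([1.0, -2.0, 0.5])
        w = np.array([0.2, 0.1, -0.4])
        assert classify_bag(z, np.zeros(3), 0.0) == pytest.approx(0.5)
        assert classify_bag(z, w, 0.3) == pytest.approx(_logistic(0.2 - 0.2 - 0.2 + 0.3))
        # p is monotone in the bias
        ps = [classify_bag(z, w, b) for b in (-2.0, 0.0, 2.0, 10.0)]
        assert ps == sorted(ps)
        with pytest.raises(ValueError):
            classify_bag(z, np.zeros(2), 0.0)


class TestMILModel:
    @pytest.mark.parametrize("agg", ["gated_attention", "max_pool"])
    def test_bag_probability_permutation_invariant(self, agg, rng):
        model = MILModel(backbone="tiny_cnn", aggregation=agg, attention_dim=8, seed=2)
        model.eval()
        bag = rng.normal(0, 0.3, size=(6, 3, 16, 16))
        p = model.predict_bag(bag).probability
        perm = rng.permutation(6)
        p_perm = model.predict_bag(bag[perm]).probability
        assert p_perm == pytest.approx(p, abs=1e-12)

    def test_attention_sums_to_one(self, rng):
        model = MILModel(backbone="tiny_cnn", seed=0)
        out = model.predict_bag(rng.normal(0, 0.3, size=(5, 3, 16, 16)))
        assert out.attention.sum() == pytest.approx(1.0, abs=1e-6)
        assert (out.attention >= 0).all()
        assert 0.0 <= out.probability <= 1.0

    def test_tiny_cnn_bag_forward_under_one_second(self, rng):
        model = MILModel(backbone="tiny_cnn", seed=0)
        model.eval()
        model.predict_bag(rng.normal(0, 0.3, size=(1, 3, 224, 224)))  # warm-up
        bag = rng.normal(0, 0.3, size=(10, 3, 224, 224))
        t0 = time.perf_counter()
        model.predict_bag(bag)
        assert time.perf_counter() - t0 < 1.0

    @pytest.mark.parametrize("agg", ["gated_attention", "max_pool"])
    def test_gradients_match_finite_differences(self, agg, rng):
        """Analytic backprop through encoder + aggregation + classifier agrees
        with central finite differences on a sample of parameters."""
        model = MILModel(backbone="tiny_cnn", aggregation=agg, attention_dim=4, seed=1)
        model.train()
        bags = [rng.normal(0, 0.3, size=(3, 3, 12, 12)), rng.normal(0, 0.3, size=(2, 3, 12, 12))]
        ys = np.array([1.0, 0.0])

        def loss():
            logits, cache = model.forward_batch(bags)
            p = sigmoid(logits)
            return float(np.mean([bag_bce(pi, yi) for pi, yi in zip(p, ys)])), p, cache

        model.zero_grad()
        _, p, cache = loss()
        model.backward_batch((p - ys) / len(ys), cache)
        eps = 1e-6
        for name, prm in model.named_parameters().items():
            flat = prm.value.ravel()
            for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _, _ = loss()
                flat[i] = old - eps
                lm, _, _ = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = prm.grad.ravel()[i]
                assert ana == pytest.approx(num, abs=5e-5, rel=5e-4), name

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = MILModel(backbone="tiny_cnn", attention_dim=16, seed=4)
        model.eval()
        bag = rng.normal(0, 0.3, size=(4, 3, 16, 16))
        p_before = model.predict_bag(bag).probability
        save_checkpoint(model, tmp_path / "model", extra={"note": "test"})
        restored = load_checkpoint(tmp_path / "model")
        assert restored.predict_bag(bag).probability == pytest.approx(p_before, abs=1e-12)
        assert restored.config() == model.config()

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            MILModel(backbone="vgg")
        with pytest.raises(ValueError):
            MILModel(aggregation="mean_pool")
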