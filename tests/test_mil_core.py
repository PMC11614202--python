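"""The attention-MIL model: scalar-loop oracle equivalence, attention
normalization, permutation invariance, likelihood loss, training and
checkpointing."""

import math

import numpy as np
import pytest

from viralmil.bags import Instance, VirusBag
from viralmil.mil_core import (
    BagPrediction,
    MILConfig,
    MILParameters,
    attention_weights,
    bag_loss,
    bag_score,
    fit,
    init_parameters,
    load_checkpoint,
    predict,
    save_checkpoint,
)

from conftest import random_bag


def scalar_loop_forward(bag, p):
    """Naive per-scalar restatement of the scoring function.

    u_m = ReLU(W1 x_m + c1); a_m = softmax_m(w . tanh(V u_m));
    theta = g(B . sum_m a_m u_m + c).
    """
    M, d = bag.features.shape
    h = p.W1.shape[0]
    L = p.V.shape[0]
    U = np.zeros((M, h))
    for m_i in range(M):
        for j in range(h):
            s = p.c1[j]
            for k in range(d):
                s += p.W1[j, k] * bag.features[m_i, k]
            U[m_i, j] = max(s, 0.0)
    e = np.zeros(M)
    for m_i in range(M):
        s = 0.0
        for l in range(L):
            t = 0.0
            for j in range(h):
                t += p.V[l, j] * U[m_i, j]
            s += p.w[l] * math.tanh(t)
        e[m_i] = s
    exp_e = np.exp(e - e.max())
    a = exp_e / exp_e.sum()
    z = np.zeros(h)
    for j in range(h):
        for m_i in range(M):
            z[j] += a[m_i] * U[m_i, j]
    if p.B.ndim == 1:
        logit = float(z @ p.B + p.c)
        theta = 1.0 / (1.0 + math.exp(-logit))
    else:
        logits = z @ p.B + p.c
        ex = np.exp(logits - logits.max())
        theta = ex / ex.sum()
    return theta, a


class TestAttentionWeights:
    def test_identical_instances_uniform(self, small_params):
        p, _ = small_params
        U = np.tile(np.abs(np.random.default_rng(0).normal(size=9)), (5, 1))
        a = attention_weights(U, p)
        np.testing.assert_allclose(a, np.full(5, 0.2), atol=1e-12)

    def test_single_instance(self, small_params):
        p, _ = small_params
        a = attention_weights(np.ones((1, 9)), p)
        assert a.shape == (1,) and a[0] == pytest.approx(1.0)

    def test_normalized_and_positive(self, small_params, rng):
        p, _ = small_params
        a = attention_weights(rng.normal(size=(7, 9)), p)
        assert (a > 0).all()
        assert a.sum() == pytest.approx(1.0, abs=1e-9)


class TestBagScoreOracle:
    @pytest.mark.parametrize("trial", range(5))
    def test_binary_forward_matches_scalar_loop(self, rng, trial):
        config = MILConfig(input_dim=6, hidden_dim=9, attention_dim=4)
        p = init_parameters(config, rng)
        bag = random_bag(rng)
        pred = bag_score(bag, p)
        theta, a = scalar_loop_forward(bag, p)
        assert pred.theta == pytest.approx(theta, abs=1e-6)
        np.testing.assert_allclose(pred.attention, a, atol=1e-6)

    def test_multiclass_forward_matches_scalar_loop(self, rng):
        config = MILConfig(input_dim=6, hidden_dim=9, attention_dim=4, n_classes=4)
        p = init_parameters(config, rng)
        bag = random_bag(rng)
        pred = bag_score(bag, p)
        theta, _ = scalar_loop_forward(bag, p)
        np.testing.assert_allclose(pred.theta, theta, atol=1e-6)
        assert np.sum(pred.theta) == pytest.approx(1.0, abs=1e-9)

    def test_zero_classifier_gives_half(self, small_params, rng):
        p, _ = small_params
        p.B = np.zeros_like(p.B)
        p.c = np.zeros_like(p.c)
        assert bag_score(random_bag(rng), p).theta == pytest.approx(0.5)

    def test_permutation_invariance(self, rng, small_params):
        p, _ = small_params
        bag = random_bag(rng, m=9)
        perm = rng.permutation(9)
        shuffled = VirusBag(bag.virus_id,
                            [bag.instances[i] for i in perm],
                            bag.features[perm], bag.label)
        pred, pred_s = bag_score(bag, p), bag_score(shuffled, p)
        assert pred.theta == pytest.approx(pred_s.theta, abs=1e-6)
        np.testing.assert_allclose(pred.attention[perm], pred_s.attention, atol=1e-6)


class TestBagLoss:
    def test_half_probability_is_ln2(self):
        preds = [BagPrediction("v", 0.5, np.array([1.0]), 0) for _ in range(3)]
        assert bag_loss(preds, [0, 1, 0]) == pytest.approx(math.log(2))

    def test_confident_correct_tends_to_zero(self):
        preds = [BagPrediction("v", 1 - 1e-9, np.array([1.0]), 1)]
        assert bag_loss(preds, [1]) < 1e-6

    def test_matches_hand_computed_bernoulli(self, rng):
        thetas = rng.uniform(0.05, 0.95, size=8)
        ys = rng.integers(0, 2, size=8)
        preds = [BagPrediction("v", t, np.array([1.0]), int(t > 0.5)) for t in thetas]
        expected = -np.mean(ys * np.log(thetas) + (1 - ys) * np.log(1 - thetas))
        assert bag_loss(preds, ys) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bag_loss([], [1])


def _separable_bags(rng, n=30, dim=8, shift=8.0):
    bags = []
    for i in range(n):
        label = i % 2
        m = int(rng.integers(2, 6))
        X = rng.normal(size=(m, dim))
        if label:
            X[0, 0] += shift
        bags.append(VirusBag(f"b{i}", [Instance(f"p{j}") for j in range(m)],
                             X, label))
    return bags


class TestFit:
    def test_separable_training_loss_small(self, rng):
        bags = _separable_bags(rng)
        config = MILConfig(input_dim=8, hidden_dim=32, attention_dim=8,
                           epochs=120, learning_rate=1e-3, weight_decay=0.0, seed=0)
        params = fit(bags, config)
        assert params.loss_trace[-1] < 0.1
        assert params.loss_trace[-1] <= params.loss_trace[0]

    def test_deterministic_given_seed(self, rng):
        bags = _separable_bags(rng, n=12)
        config = MILConfig(input_dim=8, hidden_dim=16, attention_dim=4, epochs=5, seed=3)
        p1, p2 = fit(bags, config), fit(bags, config)
        for k, a in p1.arrays().items():
            np.testing.assert_array_equal(a, p2.arrays()[k])

    def test_multiclass_head_shapes(self, rng):
        bags = []
        for i in range(20):
            m = int(rng.integers(2, 5))
            X = rng.normal(size=(m, 6))
            X[0, i % 5] += 6
            bags.append(VirusBag(f"b{i}", [Instance(f"p{j}") for j in range(m)], X, i % 5))
        config = MILConfig(input_dim=6, hidden_dim=12, attention_dim=4,
                           n_classes=5, epochs=5, seed=0)
        params = fit(bags, config)
        assert params.B.shape == (12, 5)
        pred = predict(bags[:3], params)
        for p in pred:
            assert np.sum(p.theta) == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self, rng):
        bags = [random_bag(rng, virus_id=f"v{i}", label=1) for i in range(4)]
        with pytest.raises(ValueError):
            fit(bags, MILConfig(input_dim=6))

    def test_trained_separable_predicts_training_set(self, rng):
        bags = _separable_bags(rng)
        config = MILConfig(input_dim=8, hidden_dim=32, attention_dim=8,
                           epochs=120, learning_rate=1e-3, weight_decay=0.0, seed=0)
        params = fit(bags, config)
        preds = predict(bags, params)
        acc = np.mean([p.label == b.label for p, b in zip(preds, bags)])
        assert acc == 1.0


class TestPredict:
    def test_empty_list(self, small_params):
        assert predict([], small_params[0]) == []

    def test_dimension_mismatch(self, small_params, rng):
        p, _ = small_params
        bad = random_bag(rng, dim=11)
        with pytest.raises(ValueError):
            predict([bad], p)

    def test_tie_breaks_negative(self, small_params, rng):
        p, _ = small_params
        p.B = np.zeros_like(p.B)
        p.c = np.zeros_like(p.c)
        pred = predict([random_bag(rng)], p)[0]
        assert pred.theta == pytest.approx(0.5) and pred.label == 0


class TestCheckpoint:
    def test_bit_exact_roundtrip(self, tmp_path, rng):
        config = MILConfig(input_dim=6, hidden_dim=9, attention_dim=4, seed=11)
        params = init_parameters(config, rng)
        params.loss_trace = [0.5, 0.4]
        save_checkpoint(tmp_path / "m.npz", params, config)
        loaded, loaded_cfg = load_checkpoint(tmp_path / "m.npz")
        assert loaded_cfg == config
        for k, a in params.arrays().items():
            np.testing.assert_array_equal(a, loaded.arrays()[k])
        assert loaded.loss_trace == params.loss_trace
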