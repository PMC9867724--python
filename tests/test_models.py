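"""Pooling operators and MIL heads: brute-force oracles and invariances."""

import math

import numpy as np
import pytest

from scanmil.errors import ValidationError
from scanmil.models import MILHead, Noisy2DClassifier, attention_pool, max_pool, mean_pool


def scalar_attention_oracle(X, w, V):
    """Element-by-element evaluation of the attention formula with math.*."""
    n, d = X.shape
    k = len(w)
    logits = []
    for i in range(n):
        s = 0.0
        for a in range(k):
            vx = sum(V[a][b] * X[i][b] for b in range(d))
            s += w[a] * math.tanh(vx)
        logits.append(s)
    mx = max(logits)
    exps = [math.exp(l - mx) for l in logits]
    total = sum(exps)
    att = [e / total for e in exps]
    z = [sum(att[i] * X[i][b] for i in range(n)) for b in range(d)]
    return np.array(z), np.array(att)


class TestAttentionPool:
    def test_singleton_bag(self, rng):
        x = rng.normal(size=(1, 6))
        z, a = attention_pool(x, rng.normal(size=3), rng.normal(size=(3, 6)))
        assert a == pytest.approx([1.0])
        assert z == pytest.approx(x[0])

    def test_identical_instances_share_weight(self, rng):
        x = np.tile(rng.normal(size=6), (4, 1))
        z, a = attention_pool(x, rng.normal(size=3), rng.normal(size=(3, 6)))
        assert a == pytest.approx([0.25] * 4)
        assert z == pytest.approx(x[0])

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_scalar_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n, d, k = int(rng.integers(1, 6)), int(rng.integers(1, 5)), int(rng.integers(1, 4))
        X = rng.normal(scale=2, size=(n, d))
        w = rng.normal(size=k)
        V = rng.normal(size=(k, d))
        z, a = attention_pool(X, w, V)
        z0, a0 = scalar_attention_oracle(X, w, V)
        assert np.allclose(a, a0, atol=1e-6)
        assert np.allclose(z, z0, atol=1e-6)
        assert a.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(a >= 0)

    def test_zero_w_reduces_to_mean(self, rng):
        X = rng.normal(size=(7, 5))
        z, a = attention_pool(X, np.zeros(3), rng.normal(size=(3, 5)))
        assert np.array_equal(a, np.full(7, 1.0 / 7))
        assert np.allclose(z, mean_pool(X))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            attention_pool(rng.normal(size=(3, 5)), np.zeros(2), np.zeros((2, 4)))

    def test_extreme_logits_stable(self):
        X = np.array([[1e3, 0.0], [-1e3, 0.0]])
        z, a = attention_pool(X, np.array([1e3]), np.array([[1.0, 0.0]]))
        assert np.all(np.isfinite(a)) and a.sum() == pytest.approx(1.0)


class TestMeanMaxPool:
    def test_hand_example(self):
        x = np.array([[1.0, 3.0], [3.0, 1.0]])
        assert mean_pool(x) == pytest.approx([2.0, 2.0])
        assert max_pool(x) == pytest.approx([3.0, 3.0])

    def test_singleton_identity(self, rng):
        x = rng.normal(size=(1, 9))
        assert mean_pool(x) == pytest.approx(x[0])
        assert max_pool(x) == pytest.approx(x[0])

    def test_matches_per_coordinate_loop(self, rng):
        x = rng.normal(size=(10, 512))
        mean_ref = np.array([sum(x[i, d] for i in range(10)) / 10 for d in range(512)])
        max_ref = np.array([max(x[i, d] for i in range(10)) for d in range(512)])
        assert np.allclose(mean_pool(x), mean_ref, atol=1e-12)
        assert np.array_equal(max_pool(x), max_ref)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValidationError):
            mean_pool(np.empty((0, 4)))


class TestMILHead:
    @pytest.mark.parametrize("pooling", ["attention", "mean", "max"])
    def test_permutation_invariance(self, pooling, rng):
        head = MILHead(16, pooling=pooling, hidden=12, embed=8, attn_hidden=4, seed=0)
        X = rng.normal(size=(9, 16))
        p0 = head.predict_bag(X).probability
        for _ in range(10):
            perm = rng.permutation(9)
            assert head.predict_bag(X[perm]).probability == pytest.approx(p0, abs=1e-6)

    @pytest.mark.parametrize("pooling", ["attention", "mean", "max"])
    def test_prediction_in_open_interval(self, pooling, rng):
        head = MILHead(8, pooling=pooling, hidden=6, embed=5, attn_hidden=3, seed=1)
        pred = head.predict_bag(rng.normal(size=(5, 8)))
        assert 0.0 < pred.probability < 1.0

    def test_attention_weights_normalized(self, rng):
        head = MILHead(8, pooling="attention", hidden=6, embed=5, attn_hidden=3, seed=2)
        pred = head.predict_bag(rng.normal(size=(6, 8)))
        assert pred.attention.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(pred.attention >= 0)

    def test_forward_composes_pooling_ops(self, rng):
        """Full head forward equals manual composition of FC + pooling + classifier."""
        head = MILHead(6, pooling="attention", hidden=5, embed=4, attn_hidden=3,
                       seed=3, dtype=np.float64)
        X = rng.normal(size=(3, 6))
        p = head.params
        H = np.maximum(np.maximum(X @ p["W1"] + p["b1"], 0) @ p["W2"] + p["b2"], 0)
        z, a = attention_pool(H, p["w"], p["V"])
        logit = z @ p["u"] + p["c"]
        expected = 1.0 / (1.0 + np.exp(-logit))
        pred = head.predict_bag(X)
        assert pred.probability == pytest.approx(float(expected), abs=1e-9)
        assert pred.attention == pytest.approx(a, abs=1e-9)

    def test_zero_weight_classifier_gives_constant(self, rng):
        head = MILHead(8, pooling="mean", hidden=6, embed=5, seed=4, dtype=np.float64)
        head.params["u"][...] = 0.0
        head.params["c"][...] = 0.3
        p1 = head.predict_bag(rng.normal(size=(4, 8))).probability
        p2 = head.predict_bag(rng.normal(size=(11, 8))).probability
        expected = 1.0 / (1.0 + np.exp(-0.3))
        assert p1 == pytest.approx(expected, abs=1e-9)
        assert p2 == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("pooling", ["attention", "mean", "max"])
    def test_gradients_match_finite_differences(self, pooling):
        rng = np.random.default_rng(0)
        head = MILHead(6, pooling=pooling, hidden=5, embed=4, attn_hidden=3,
                       dropout=0.0, seed=3, init_std=0.5, dtype=np.float64)
        X = rng.normal(size=(4, 6))
        y = 1
        prob, _, cache = head._forward(X, training=False)
        grads = head._backward(cache, prob - y)
        eps = 1e-6
        for name, v in head.params.items():
            it = np.nditer(v, flags=["multi_index"])
            num = np.zeros_like(v)
            for _ in it:
                i = it.multi_index
                orig = v[i]
                v[i] = orig + eps
                lp = head.loss(X, y)
                v[i] = orig - eps
                lm = head.loss(X, y)
                v[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            scale = np.max(np.abs(num)) + 1e-12
            assert np.max(np.abs(num - grads[name])) / scale < 1e-5, name

    def test_parameter_count_formula(self):
        d_raw, h, e, k = 1472, 512, 512, 128
        head = MILHead(d_raw, hidden=h, embed=e, attn_hidden=k)
        expected = (d_raw * h + h) + (h * e + e) + (k * e + k) + (e + 1)
        assert head.n_parameters() == expected
        # transfer configuration lands near the ~1.1M scale of a compact head
        assert 1.0e6 < expected < 1.3e6

    def test_empty_bag_rejected(self):
        head = MILHead(4, hidden=3, embed=3, attn_hidden=2)
        with pytest.raises(ValidationError):
            head.predict_bag(np.empty((0, 4)))

    def test_training_reduces_loss_on_separable_toy(self, rng):
        head = MILHead(4, pooling="attention", hidden=8, embed=8, attn_hidden=4,
                       dropout=0.0, lr=1e-2, seed=0)
        bags = []
        for i in range(30):
            y = i % 2
            X = rng.normal(size=(6, 4))
            if y:
                X[rng.integers(6)] += np.array([4.0, 4.0, 0, 0])
            bags.append((X, y))
        first = np.mean([head.loss(X, y) for X, y in bags])
        g = np.random.default_rng(0)
        for _ in range(30):
            for X, y in bags:
                head.train_step(X, y, g)
        assert np.mean([head.loss(X, y) for X, y in bags]) < first


class TestNoisy2D:
    def test_mean_aggregation_of_slice_probs(self, rng):
        model = Noisy2DClassifier(6, hidden=5, embed=4, seed=0, dtype=np.float64)
        X = rng.normal(size=(2, 6))
        probs = model.slice_probabilities(X)
        assert model.predict_bag(X).probability == pytest.approx(probs.mean())
        model.aggregate = "max"
        assert model.predict_bag(X).probability == pytest.approx(probs.max())

    def test_broadcast_labels_disagree_with_slice_truth(self, small_cohort):
        """Broadcasting the scan label marks clean slices of positive scans wrong."""
        _, pairs = small_cohort
        disagreements = 0
        total = 0
        for _, truth in pairs:
            broadcast = np.full(truth.n_slices, truth.scan_label)
            disagreements += int((broadcast != truth.slice_labels).sum())
            total += truth.n_slices
        # positive scans have lesion_fraction ~0.3, so false-positive slices abound
        assert disagreements > 0
        pos_pairs = [t for _, t in pairs if t.scan_label == 1]
        assert all((t.slice_labels == 0).any() for t in pos_pairs)
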