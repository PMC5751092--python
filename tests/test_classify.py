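"""ELM and MLP classifier behavior, including the closed-form ELM theory."""

import numpy as np
import pytest

from sistdetect.classify import (ELMClassifier, MLPClassifier,
                                 select_hidden_neurons)


def _separable_blobs(n, d, seed, gap=4.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(-gap / 2, 1.0, size=(half, d)),
                   rng.normal(gap / 2, 1.0, size=(n - half, d))])
    y = np.concatenate([-np.ones(half), np.ones(n - half)])
    return X, y


class TestELM:
    def test_zero_training_error_at_L_equals_N(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        y = np.where(rng.random(40) < 0.5, -1.0, 1.0)
        clf = ELMClassifier(n_hidden=40, random_state=1).fit(X, y)
        scores = clf.decision_function(X)
        assert np.sum(np.abs(scores - y)) < 1e-6
        assert np.array_equal(clf.predict(X), y)

    def test_seeded_determinism(self):
        X, y = _separable_blobs(30, 4, seed=2)
        a = ELMClassifier(n_hidden=20, random_state=9).fit(X, y)
        b = ELMClassifier(n_hidden=20, random_state=9).fit(X, y)
        np.testing.assert_array_equal(a.output_weights_, b.output_weights_)
        np.testing.assert_array_equal(a.input_weights_, b.input_weights_)

    def test_rejects_more_neurons_than_samples(self):
        X, y = _separable_blobs(20, 3, seed=3)
        with pytest.raises(ValueError):
            ELMClassifier(n_hidden=21).fit(X, y)

    def test_zero_output_weights_predict_positive_class(self):
        X, y = _separable_blobs(20, 3, seed=4)
        clf = ELMClassifier(n_hidden=5, random_state=0).fit(X, y)
        clf.output_weights_ = np.zeros_like(clf.output_weights_)
        scores = clf.decision_function(X)
        assert np.all(scores == 0)
        # score >= 0 maps to the positive class by convention
        assert np.all(clf.predict(X) == clf.classes_[1])

    def test_rowwise_independence_under_permutation(self):
        X, y = _separable_blobs(24, 5, seed=5)
        clf = ELMClassifier(n_hidden=10, random_state=1).fit(X, y)
        perm = np.random.default_rng(0).permutation(24)
        np.testing.assert_allclose(clf.decision_function(X)[perm],
                                   clf.decision_function(X[perm]))

    def test_training_row_permutation_invariance(self):
        X, y = _separable_blobs(30, 4, seed=6)
        perm = np.random.default_rng(1).permutation(30)
        a = ELMClassifier(n_hidden=12, random_state=3).fit(X, y)
        b = ELMClassifier(n_hidden=12, random_state=3).fit(X[perm], y[perm])
        np.testing.assert_allclose(a.output_weights_, b.output_weights_,
                                   atol=1e-8)

    def test_residual_non_increasing_in_L(self):
        """Shared seeds give prefix-nested hidden layers, so the training
        residual can only shrink as neurons are added."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 6))
        y = np.where(rng.random(60) < 0.5, -1.0, 1.0)
        prev = np.inf
        for L in (5, 10, 20, 40, 60):
            clf = ELMClassifier(n_hidden=L, random_state=11).fit(X, y)
            H = 1.0 / (1.0 + np.exp(-(X @ clf.input_weights_.T + clf.biases_)))
            resid = np.linalg.norm(H @ clf.output_weights_ - y)
            assert resid <= prev + 1e-9
            prev = resid

    def test_balanced_weighting_recovers_minority_class(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, size=(190, 3)),
                       rng.normal(5, 1, size=(10, 3))])
        y = np.concatenate([np.zeros(190), np.ones(10)])
        clf = ELMClassifier(n_hidden=30, random_state=0,
                            class_weight="balanced").fit(X, y)
        assert np.all(clf.predict(X[-10:]) == 1)


class TestMLP:
    def test_xor_is_learnable(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        wins = 0
        for seed in range(5):
            clf = MLPClassifier(n_hidden=4, learning_rate=0.5,
                                momentum=0.9, max_epochs=2000,
                                validation_fraction=0.0,
                                random_state=seed).fit(X, y)
            wins += int(np.array_equal(clf.predict(X), y))
        assert wins >= 4

    def test_seeded_determinism(self):
        X, y = _separable_blobs(40, 3, seed=9)
        y = (y > 0).astype(int)
        kw = dict(n_hidden=6, max_epochs=50, random_state=21)
        a = MLPClassifier(**kw).fit(X, y)
        b = MLPClassifier(**kw).fit(X, y)
        np.testing.assert_array_equal(a.hidden_weights_, b.hidden_weights_)
        np.testing.assert_array_equal(a.output_weights_, b.output_weights_)

    def test_linearly_separable_blobs(self):
        X, y = _separable_blobs(60, 2, seed=10)
        y = (y > 0).astype(int)
        # independent oracle: the data is linearly separable
        from sklearn.linear_model import LogisticRegression
        oracle = LogisticRegression().fit(X, y)
        assert oracle.score(X, y) == 1.0
        clf = MLPClassifier(n_hidden=2, learning_rate=0.5, max_epochs=1000,
                            validation_fraction=0.0, random_state=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_rejects_invalid_hidden_count(self):
        with pytest.raises(ValueError):
            MLPClassifier(n_hidden=0).fit(np.zeros((4, 2)), [0, 1, 0, 1])

    def test_full_batch_row_permutation_stability(self):
        X, y = _separable_blobs(50, 3, seed=12)
        y = (y > 0).astype(int)
        perm = np.random.default_rng(2).permutation(50)
        kw = dict(n_hidden=4, max_epochs=100, validation_fraction=0.0,
                  random_state=5)
        a = MLPClassifier(**kw).fit(X, y)
        b = MLPClassifier(**kw).fit(X[perm], y[perm])
        np.testing.assert_allclose(a.hidden_weights_, b.hidden_weights_,
                                   atol=1e-6)

    def test_cross_check_against_reference_mlp(self):
        """A reference backprop implementation solves the same separable
        problem; ours must match its perfect training accuracy."""
        from sklearn.neural_network import MLPClassifier as SkMLP
        X, y = _separable_blobs(80, 4, seed=13)
        y = (y > 0).astype(int)
        ref = SkMLP(hidden_layer_sizes=(4,), activation="logistic",
                    solver="sgd", learning_rate_init=0.5, momentum=0.9,
                    max_iter=1000, random_state=0).fit(X, y)
        ours = MLPClassifier(n_hidden=4, learning_rate=0.5, max_epochs=1000,
                             validation_fraction=0.0, random_state=0).fit(X, y)
        assert ref.score(X, y) == 1.0
        assert np.mean(ours.predict(X) == y) == 1.0


class TestSelectHiddenNeurons:
    def test_singleton_grid(self):
        X, y = _separable_blobs(40, 3, seed=14)
        assert select_hidden_neurons(X, y, [7], "elm", seed=0) == 7

    def test_ties_take_smaller_count(self):
        # a trivially separable problem: every grid value reaches zero error
        X, y = _separable_blobs(100, 2, seed=15, gap=10.0)
        best = select_hidden_neurons(X, y, [40, 10, 20], "elm", seed=0)
        assert best == 10

    def test_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            select_hidden_neurons(np.zeros((10, 2)), np.zeros(10), [], "elm")
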