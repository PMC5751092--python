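"""Mutual information, mRMR ranking and forward selection, with brute-force
oracles on small instances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sistdetect.select import (SelectedFeatureSet, discretize, forward_select,
                               mrmr_rank, mutual_information)


class TestMutualInformation:
    def test_identical_binary_uniform_is_one_bit(self):
        x = np.repeat([0, 1], 500)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_exact_independence_is_zero(self):
        # product contingency table 25/25/25/25
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile(np.repeat([0, 1], 25), 2)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_evaluated_sum(self):
        # joint counts [[40, 10], [10, 40]]
        x = np.repeat([0, 0, 1, 1], [40, 10, 10, 40])
        y = np.concatenate([np.zeros(40), np.ones(10), np.zeros(10), np.ones(40)])
        expected = sum(
            c / 100 * np.log2((c / 100) / 0.25)
            for c in (40, 10, 10, 40))
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_symmetry_self_information_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 200)
        y = rng.integers(0, 3, 200)
        ixy = mutual_information(x, y)
        assert ixy == pytest.approx(mutual_information(y, x))
        assert ixy >= 0
        p = np.bincount(x) / x.size
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mutual_information(x, x) == pytest.approx(entropy)

    def test_matches_reference_library(self):
        from sklearn.metrics import mutual_info_score
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, 500)
        y = rng.integers(0, 4, 500)
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / np.log(2))


def _relv_redn(codes, y, subset):
    relv = np.mean([mutual_information(codes[:, j], y) for j in subset])
    redn = np.mean([mutual_information(codes[:, i], codes[:, j])
                    for i in subset for j in subset])
    return relv - redn


class TestMRMRRank:
    def test_redundant_copy_ranked_below_noise(self):
        """A duplicate of the top feature scores relevance - H(f1) < 0 at
        the second step, so independent noise (score ~ 0) outranks it."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        flip = rng.random(400) < 0.1
        f1 = np.where(flip, 1 - y, y)   # strongly relevant, not a copy of c
        f2 = f1.copy()                  # exact duplicate: fully redundant
        f3 = rng.integers(0, 2, 400)    # independent noise
        X = np.column_stack([f1, f2, f3]).astype(np.uint8)
        order = mrmr_rank(X, y, 3, discretized=True)
        assert order[0] == 0
        assert order.index(2) < order.index(1)

    def test_m_equals_one_is_relevance_argmax(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 300)
        X = rng.integers(0, 5, size=(300, 6)).astype(np.uint8)
        X[:, 4] = (y + rng.integers(0, 5, 300)) % 5   # strongest feature
        order = mrmr_rank(X, y, 1, discretized=True)
        best = max(range(6),
                   key=lambda j: mutual_information(X[:, j], y))
        assert order == [best]

    def test_rejects_m_larger_than_columns(self):
        with pytest.raises(ValueError):
            mrmr_rank(np.zeros((10, 3)), np.zeros(10), 4)

    def test_agrees_with_exhaustive_subset_search(self):
        """Greedy incremental mRMR finds the brute-force optimum of
        Relv - Redn on most small random instances."""
        hits = 0
        n_instances = 50
        for seed in range(n_instances):
            rng = np.random.default_rng(seed)
            n = 1000
            y = rng.integers(0, 2, n)
            # four informative features of distinct strength, four noise
            mixes = [0.75, 0.65, 0.55, 0.45, 0.0, 0.0, 0.0, 0.0]
            cols = rng.permutation(8)
            X = np.empty((n, 8), dtype=np.uint8)
            for j, col in enumerate(cols):
                noise = rng.integers(0, 2, n)
                X[:, col] = np.where(rng.random(n) < mixes[j], y, noise)
            greedy = set(mrmr_rank(X, y, 4, discretized=True))
            best_subset, best_score = None, -np.inf
            for subset in itertools.combinations(range(8), 4):
                score = _relv_redn(X, y, subset)
                if score > best_score:
                    best_subset, best_score = set(subset), score
            if greedy == best_subset:
                hits += 1
        assert hits >= 0.9 * n_instances

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        X = rng.integers(0, 10, size=(300, 6)).astype(np.uint8)
        X[:, 2] = y * 5 + rng.integers(0, 5, 300)
        order = mrmr_rank(X, y, 6, discretized=True)
        perm = [5, 3, 0, 1, 4, 2]
        Xp = X[:, perm]
        order_p = mrmr_rank(Xp, y, 6, discretized=True)
        assert [perm[j] for j in order_p] == order


class TestForwardSelect:
    def test_keeps_improving_prefix(self):
        """With a deterministic stub scorer, exactly the improving
        candidates are kept and scanning stops after the patience."""
        calls = []

        class Stub:
            def __init__(self):
                self.cols = None

            def fit(self, X, y):
                self.cols = X.shape[1]
                return self

            def predict(self, X):
                calls.append(self.cols)
                # F1 improves for up to 3 features, then flattens
                frac = min(self.cols, 3) / 3.0
                n = X.shape[0]
                k = int(round(frac * n))
                return np.concatenate([np.ones(k), np.zeros(n - k)])

        y_val = np.ones(30)
        X = np.zeros((40, 12))
        ranked = list(range(12))
        kept = forward_select(ranked, X, np.ones(40), np.zeros((30, 12)),
                              y_val, classifier_factory=Stub, patience=5)
        assert kept == [0, 1, 2]
        # 3 kept + 5 consecutive failures afterwards
        assert len(calls) == 1 + 2 + 5

    def test_floor_of_one_feature(self):
        class Useless:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(X.shape[0])

        kept = forward_select(list(range(8)), np.zeros((10, 8)),
                              np.ones(10), np.zeros((10, 8)), np.ones(10),
                              classifier_factory=Useless, patience=3)
        assert kept == [0]

    def test_rejects_empty_ranking(self):
        with pytest.raises(ValueError):
            forward_select([], np.zeros((5, 2)), np.zeros(5),
                           np.zeros((5, 2)), np.zeros(5))


class TestSelectedFeatureSet:
    def test_subset_invariant(self):
        with pytest.raises(ValueError):
            SelectedFeatureSet(mrmr_order=[0, 1], selected=[2], mi_bins=10)

    def test_json_round_trip(self, tmp_path):
        s = SelectedFeatureSet(mrmr_order=[3, 1, 2], selected=[3, 2],
                               mi_bins=10, relevance=[0.5, 0.2, 0.1])
        path = tmp_path / "sel.json"
        s.to_json(path)
        assert SelectedFeatureSet.from_json(path) == s


class TestDiscretize:
    def test_training_bounds_reused(self):
        X = np.array([[0.0], [10.0]])
        codes = discretize(np.array([[5.0]]), bins=10,
                           bounds=(np.array([0.0]), np.array([10.0])))
        assert codes[0, 0] == 5
        assert discretize(X, bins=10).ravel().tolist() == [0, 9]
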