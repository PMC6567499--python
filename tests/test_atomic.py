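import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drcomb import (
    AtomicClassifier,
    ExpressionDataset,
    FeatureSubset,
    enumerate_restricted_pairs,
    enumerate_subsets,
    fit_atomic,
    fit_atomic_pool,
    rank_transform_fit_apply,
)


def _labeled(X, y):
    X = np.asarray(X, dtype=float)
    return ExpressionDataset(
        [f"s{i}" for i in range(X.shape[0])],
        [f"g{j}" for j in range(X.shape[1])],
        X,
        labels=np.asarray(y, dtype=int),
    )


def brute_force_knn(ref, labels, query, k, exclude_idx=None):
    """Independent oracle: full stable sort by (distance, index)."""
    d = ((ref - query[None, :]) ** 2).sum(axis=1).astype(float)
    if exclude_idx is not None:
        d[exclude_idx] = np.inf
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    votes = int(np.asarray(labels)[order].sum())
    return votes, int(2 * votes > k)


class TestEnumeration:
    def test_full_enumeration_small(self):
        subs = enumerate_subsets(3, 2)
        assert [s.indices for s in subs] == [
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2)
        ]

    def test_singles_only(self):
        assert len(enumerate_subsets(4, 1)) == 4

    @pytest.mark.parametrize("p,order", [(5, 2), (10, 3), (50, 2), (7, 3)])
    def test_counts_match_binomials(self, p, order):
        expected = sum(math.comb(p, s) for s in range(1, order + 1))
        assert len(enumerate_subsets(p, order)) == expected

    def test_paper_scale_pair_count(self):
        # 343 features: 343 singles + 58,653 distinct pairs
        assert len(enumerate_subsets(343, 2)) == 58_996

    def test_restricted_pairs(self):
        assert [s.indices for s in enumerate_restricted_pairs([0, 1])] == [
            (0, 1)
        ]
        assert enumerate_restricted_pairs([]) == []
        assert len(enumerate_restricted_pairs([2, 4, 6, 8, 10])) == 10

    def test_invalid_subsets(self):
        with pytest.raises(ValueError):
            FeatureSubset((2, 1))
        with pytest.raises(ValueError):
            FeatureSubset((0, 1, 2, 3))
        with pytest.raises(ValueError):
            enumerate_subsets(2, 3)


class TestFitAtomic:
    def test_fit_shapes(self, balanced_dataset):
        ac = fit_atomic(balanced_dataset, (0, 1), k=7)
        assert ac.reference_points.shape == (20, 2)
        assert ac.k == 7

    def test_even_k_rejected(self, balanced_dataset):
        with pytest.raises(ValueError, match="odd"):
            fit_atomic(balanced_dataset, (0,), k=4)

    def test_k_exceeding_training_rejected(self):
        ds = _labeled([[0.0], [1.0]], [0, 1])
        with pytest.raises(ValueError):
            fit_atomic(ds, (0,), k=3)


class TestClassify:
    def test_k1_self_query(self):
        ds = _labeled([[0.0], [5.0], [9.0]], [1, 0, 1])
        ac = fit_atomic(ds, (0,), k=1)
        assert ac.classify(np.array([5.0, ])) == 0
        assert ac.classify(np.array([0.0])) == 1

    def test_three_nearest_majority(self):
        ds = _labeled([[0.0], [0.0], [10.0]], [0, 0, 1])
        ac = fit_atomic(ds, (0,), k=3)
        assert ac.classify(np.array([1.0])) == 0

    def test_neighbors_straddle_query(self):
        ds = _labeled([[-1.0], [0.0], [1.0], [2.0]], [0, 0, 1, 1])
        ac = fit_atomic(ds, (0,), k=3)
        # neighbors of 0.6 are {0, 1, 2} -> labels {0,1,1} -> majority 1
        assert ac.classify(np.array([0.6])) == 1
        # at 0.5 the third neighbor is a -1/2 distance tie, resolved to the
        # lower reference index (-1, label 0) -> majority 0
        assert ac.classify(np.array([0.5])) == 0

    def test_score_counts_class1_neighbors(self):
        ds = _labeled([[float(i)] for i in range(7)], [1, 1, 0, 1, 0, 0, 1])
        ac = fit_atomic(ds, (0,), k=7)
        assert ac.score(np.array([3.0])) == 4

    def test_all_class0_scores_zero(self):
        rng = np.random.default_rng(0)
        ds = _labeled(rng.standard_normal((9, 2)), np.zeros(9))
        ac = fit_atomic(ds, (0, 1), k=5)
        for q in rng.standard_normal((10, 2)):
            assert ac.score(q) == 0

    def test_majority_consistent_with_score(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(7, 15))
            ds = _labeled(
                rng.standard_normal((n, 2)), rng.integers(0, 2, n)
            )
            ac = fit_atomic(ds, (0, 1), k=7)
            q = rng.standard_normal(2)
            assert ac.classify(q) == int(ac.score(q) / 7 >= 0.5)

    def test_full_row_queries_sliced_by_subset(self, balanced_dataset):
        ac = fit_atomic(balanced_dataset, (1, 3), k=5)
        full_row = balanced_dataset.values[4]
        sub_row = full_row[[1, 3]]
        assert ac.classify(full_row) == ac.classify(sub_row)


class TestOracleAgreement:
    @pytest.mark.parametrize("metric", ["euclidean", "rank"])
    @pytest.mark.parametrize("k", [1, 3, 7, 9])
    def test_matches_brute_force(self, metric, k):
        rng = np.random.default_rng(k * 17 + (metric == "rank"))
        for _ in range(60):
            n = int(rng.integers(k, 16)) + 1
            p = int(rng.integers(1, 4))
            # discretized values force distance ties
            X = np.round(rng.standard_normal((n, p)), 1)
            y = rng.integers(0, 2, n)
            ds = _labeled(X, y)
            subset = tuple(sorted(rng.choice(p, min(p, 2), replace=False)))
            ac = fit_atomic(ds, subset, k=k, metric=metric)
            q_raw = np.round(rng.standard_normal(p), 1)[list(subset)]
            if metric == "rank":
                q = np.array([
                    rank_transform_fit_apply(X[:, f], q_raw[i])
                    for i, f in enumerate(subset)
                ])
            else:
                q = q_raw
            votes, call = brute_force_knn(
                ac.reference_points, y, np.atleast_1d(q), k
            )
            assert ac.score(q_raw) == votes
            assert ac.classify(q_raw) == call

    def test_self_exclusion_matches_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(6, 12))
            X = np.round(rng.standard_normal((n, 2)), 1)
            y = rng.integers(0, 2, n)
            ds = _labeled(X, y)
            ac = fit_atomic(ds, (0, 1), k=3)
            i = int(rng.integers(n))
            votes, call = brute_force_knn(X, y, X[i], 3, exclude_idx=i)
            assert ac.score(X[i], include_self=False) == votes
            assert ac.classify(X[i], include_self=False) == call

    def test_pool_agrees_with_single_classifiers(self, balanced_dataset):
        subsets = enumerate_subsets(5, 2)
        pool = fit_atomic_pool(balanced_dataset, subsets, k=7, metric="rank")
        rng = np.random.default_rng(2)
        Q = rng.standard_normal((6, 5))
        batch = pool.classify(Q)
        for i in range(len(pool)):
            ac = pool[i]
            for j, q in enumerate(Q):
                assert batch[i, j] == ac.classify(q)


class TestRankTransform:
    def test_query_equal_to_training_value(self):
        assert rank_transform_fit_apply(np.array([5.0, 1.0, 3.0]), 3.0) == 2.0

    def test_query_above_all(self):
        assert (
            rank_transform_fit_apply(np.array([1.0, 2.0, 3.0, 4.0]), 10.0)
            == 5.0
        )

    def test_training_points_map_to_average_ranks(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(9)
        train = np.round(rng.standard_normal(20), 1)
        expected = rankdata(train, method="average")
        got = rank_transform_fit_apply(train, train)
        np.testing.assert_allclose(got, expected)

    def test_monotone_between_training_values(self):
        train = np.array([0.0, 1.0, 2.0])
        qs = np.array([-5.0, 0.0, 0.5, 1.0, 1.5, 2.0, 7.0])
        ranks = rank_transform_fit_apply(train, qs)
        assert (np.diff(ranks) >= 0).all()

    def test_empty_training_error(self):
        with pytest.raises(ValueError):
            rank_transform_fit_apply(np.array([]), 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 5.0),
        shift=st.floats(-10.0, 10.0),
    )
    def test_rank_metric_invariant_to_monotone_transform(
        self, seed, scale, shift
    ):
        """Classifications are unchanged by strictly increasing transforms."""
        rng = np.random.default_rng(seed)
        n = 11
        X = rng.standard_normal((n, 2))
        y = rng.integers(0, 2, n)
        Q = rng.standard_normal((4, 2))

        def transform(a):
            out = a.copy()
            out[:, 0] = np.exp(scale * a[:, 0])
            out[:, 1] = scale * a[:, 1] ** 3 + shift
            return out

        base = fit_atomic_pool(
            _labeled(X, y), enumerate_subsets(2, 2), k=3, metric="rank"
        )
        warped = fit_atomic_pool(
            _labeled(transform(X), y), enumerate_subsets(2, 2), k=3,
            metric="rank",
        )
        np.testing.assert_array_equal(
            base.classify(Q), warped.classify(transform(Q))
        )
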