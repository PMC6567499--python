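"""kNN atomic classifiers on small feature subsets.

An *atomic classifier* is a k-nearest-neighbor classifier restricted to a
tiny feature subset (a single feature, a pair, or a triplet). Thousands of
them are enumerated, filtered by training accuracy, and combined; they are
the information-abstraction layer of the hierarchy.

Two metrics are supported: plain Euclidean distance on the raw feature
values, and a rank variant in which each feature is replaced by its rank
within the atomic classifier's own training set (queries are mapped onto
the same rank scale), making the classifier invariant to any strictly
monotone per-feature transform — useful when features live on wildly
different scales.

:class:`AtomicPool` is the array-backed batch form used by the pipeline: it
holds one shared (transformed) training matrix and an (S, width) array of
subsets, and evaluates all S classifiers on a query block in one vectorized
pass. :class:`AtomicClassifier` is the single-classifier view.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _knn
from .data_model import ExpressionDataset

__all__ = [
    "FeatureSubset",
    "AtomicClassifier",
    "AtomicPool",
    "enumerate_subsets",
    "enumerate_restricted_pairs",
    "fit_atomic",
    "fit_atomic_pool",
    "atomic_classify",
    "knn_score",
    "rank_transform_fit_apply",
]


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered subset of 1-3 distinct feature column indices."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if not 1 <= len(idx) <= 3:
            raise ValueError("subset size must be 1, 2 or 3")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        if min(idx) < 0:
            raise ValueError("negative feature index")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


def enumerate_subsets(n_features: int, max_order: int) -> list[FeatureSubset]:
    """All feature subsets of sizes 1..max_order in lexicographic order.

    The count is sum_{s=1}^{max_order} C(n_features, s); e.g. 343 features
    with max_order=2 give 343 singles + 58,653 pairs = 58,996 subsets.
    """
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    if max_order > n_features:
        raise ValueError("max_order exceeds number of features")
    out: list[FeatureSubset] = []
    for order in range(1, max_order + 1):
        out.extend(
            FeatureSubset(c)
            for c in itertools.combinations(range(n_features), order)
        )
    return out


def enumerate_restricted_pairs(
    passing_singles: Sequence[int],
) -> list[FeatureSubset]:
    """All pairs over the features whose single-feature classifiers passed.

    This is the hierarchical enumeration used when very many noise features
    are present: pairs are considered only when both members already showed
    single-feature classification power, keeping the pair count tractable.
    """
    singles = sorted(int(i) for i in passing_singles)
    if len(set(singles)) != len(singles):
        raise ValueError("passing_singles must be distinct")
    return [FeatureSubset(c) for c in itertools.combinations(singles, 2)]


def rank_transform_fit_apply(
    train_values: np.ndarray, query_value: float | np.ndarray
) -> float | np.ndarray:
    """Rank-scale mapping for one feature.

    Training values take their average-tie ranks; a query maps to
    (#train values strictly below) + (#equal + 1)/2 when it ties training
    values (so a training point maps to its own rank) and to
    (#below) + 1 otherwise.
    """
    if len(train_values) == 0:
        raise ValueError("train_values must be non-empty")
    return _knn.rank_apply(_knn.rank_fit(train_values), query_value)


class AtomicPool:
    """A batch of atomic classifiers sharing one training set.

    All classifiers use the same k and metric; they differ only in their
    feature subsets. The training matrix is stored once (rank-transformed
    per feature when metric="rank"), and queries are evaluated for all
    subsets in a vectorized sweep.
    """

    def __init__(
        self,
        subsets: Sequence[FeatureSubset],
        k: int,
        metric: str,
        train_values: np.ndarray,
        train_labels: np.ndarray,
        feature_ids: Optional[list[str]] = None,
    ):
        if metric not in ("euclidean", "rank"):
            raise ValueError(f"unknown metric {metric!r}")
        if k % 2 == 0 or k < 1:
            raise ValueError("k must be a positive odd integer")
        n = train_values.shape[0]
        if k > n:
            raise ValueError(f"k={k} exceeds training size {n}")
        if train_labels.shape != (n,):
            raise ValueError("labels length mismatch")
        self.subsets = list(subsets)
        self.k = int(k)
        self.metric = metric
        self.feature_ids = feature_ids
        self.raw_train = np.asarray(train_values, dtype=float)
        self.train_labels = np.asarray(train_labels, dtype=int)
        self._labels_mask = self.train_labels.astype(bool)
        p = self.raw_train.shape[1]
        if self.subsets and max(max(s) for s in self.subsets) >= p:
            raise ValueError("subset index out of range")
        if metric == "rank":
            self._rank_sorted = np.sort(self.raw_train, axis=0)
            self.ref = np.empty_like(self.raw_train)
            for j in range(p):
                self.ref[:, j] = _knn.rank_apply(
                    self._rank_sorted[:, j], self.raw_train[:, j]
                )
        else:
            self._rank_sorted = None
            self.ref = self.raw_train
        width = max((len(s) for s in self.subsets), default=1)
        self._padded = np.full((len(self.subsets), width), p, dtype=np.intp)
        for i, s in enumerate(self.subsets):
            self._padded[i, : len(s)] = s.indices
        self._dtype = np.float32 if metric == "rank" else np.float64

    def __len__(self) -> int:
        return len(self.subsets)

    @property
    def n_train(self) -> int:
        return self.raw_train.shape[0]

    def transform_queries(self, queries: np.ndarray) -> np.ndarray:
        """Map raw query rows onto the pool's (possibly rank) coordinates."""
        q = np.asarray(queries, dtype=float)
        if q.ndim == 1:
            q = q[None, :]
        if q.shape[1] != self.raw_train.shape[1]:
            raise ValueError(
                f"query has {q.shape[1]} features, expected "
                f"{self.raw_train.shape[1]}"
            )
        if self.metric == "rank":
            out = np.empty_like(q)
            for j in range(q.shape[1]):
                out[:, j] = _knn.rank_apply(self._rank_sorted[:, j], q[:, j])
            return out
        return q

    def votes(
        self,
        queries: np.ndarray,
        exclude_self: Optional[np.ndarray] = None,
        transformed: bool = False,
    ) -> np.ndarray:
        """Class-1 neighbor counts, shape (n_subsets, n_queries).

        ``exclude_self`` gives, per query, the training-row index to drop
        from the reference set (-1 for none).
        """
        q = queries if transformed else self.transform_queries(queries)
        if len(self.subsets) == 0:
            return np.zeros((0, q.shape[0]), dtype=np.int32)
        return _knn.subset_votes(
            self.ref,
            np.asarray(q),
            self._padded,
            self._labels_mask,
            self.k,
            exclude=exclude_self,
            dtype=self._dtype,
        )

    def classify(
        self,
        queries: np.ndarray,
        exclude_self: Optional[np.ndarray] = None,
        transformed: bool = False,
    ) -> np.ndarray:
        """Majority-vote binary calls, shape (n_subsets, n_queries)."""
        v = self.votes(queries, exclude_self=exclude_self, transformed=transformed)
        return (2 * v > self.k).astype(np.int8)

    def training_classifications(self, include_self: bool = True) -> np.ndarray:
        """Binary calls of every classifier on its own training set."""
        excl = None if include_self else np.arange(self.n_train)
        return self.classify(self.raw_train, exclude_self=excl)

    def select(self, keep: Sequence[int] | np.ndarray) -> "AtomicPool":
        """Sub-pool with a subset of the classifiers (shared training data)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        new = AtomicPool.__new__(AtomicPool)
        new.subsets = [self.subsets[i] for i in keep]
        new.k = self.k
        new.metric = self.metric
        new.feature_ids = self.feature_ids
        new.raw_train = self.raw_train
        new.train_labels = self.train_labels
        new._labels_mask = self._labels_mask
        new._rank_sorted = self._rank_sorted
        new.ref = self.ref
        new._padded = self._padded[keep] if len(self._padded) else self._padded
        new._dtype = self._dtype
        return new

    def __getitem__(self, i: int) -> "AtomicClassifier":
        s = self.subsets[i]
        cols = list(s.indices)
        rank_maps = None
        if self.metric == "rank":
            rank_maps = [self._rank_sorted[:, j].copy() for j in cols]
        return AtomicClassifier(
            subset=s,
            k=self.k,
            metric=self.metric,
            reference_points=self.ref[:, cols].copy(),
            reference_labels=self.train_labels.copy(),
            rank_maps=rank_maps,
            n_total_features=self.raw_train.shape[1],
        )


@dataclass
class AtomicClassifier:
    """A single kNN classifier on a small feature subset.

    ``reference_points`` are the training samples restricted to the subset,
    already rank-transformed when metric="rank" (``rank_maps`` holds the
    per-feature sorted training values needed to map queries).
    """

    subset: FeatureSubset
    k: int
    metric: str
    reference_points: np.ndarray
    reference_labels: np.ndarray
    rank_maps: Optional[list[np.ndarray]] = None
    n_total_features: Optional[int] = None

    def __post_init__(self) -> None:
        self.reference_points = np.asarray(self.reference_points, dtype=float)
        self.reference_labels = np.asarray(self.reference_labels, dtype=int)
        n = self.reference_points.shape[0]
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be a positive odd integer")
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds reference count {n}")
        if self.reference_labels.shape != (n,):
            raise ValueError("reference_labels length mismatch")
        if self.metric == "rank" and self.rank_maps is None:
            raise ValueError("rank metric requires rank_maps")

    def _query_coords(self, query_row: np.ndarray) -> np.ndarray:
        q = np.asarray(query_row, dtype=float).ravel()
        s = len(self.subset)
        if self.n_total_features is not None and q.size == self.n_total_features:
            vals = q[list(self.subset.indices)]
        elif q.size == s:
            vals = q
        else:
            raise ValueError(
                f"query length {q.size} matches neither the subset size {s} "
                f"nor the full feature count {self.n_total_features}"
            )
        if self.metric == "rank":
            vals = np.array(
                [
                    _knn.rank_apply(self.rank_maps[j], vals[j])
                    for j in range(s)
                ]
            )
        return vals

    def score(self, query_row: np.ndarray, include_self: bool = True) -> int:
        """Number of class-1 labels among the k nearest reference points."""
        q = self._query_coords(query_row)
        d = ((self.reference_points - q[None, :]) ** 2).sum(axis=1)[None, :]
        exclude = None
        if not include_self:
            matches = np.flatnonzero(
                (self.reference_points == q[None, :]).all(axis=1)
            )
            if matches.size:
                exclude = np.array([matches[0]])
        return int(
            _knn.votes_from_dists(
                d, self.reference_labels.astype(bool), self.k, exclude
            )[0]
        )

    def classify(self, query_row: np.ndarray, include_self: bool = True) -> int:
        """Majority-vote class call in {0, 1}."""
        return int(2 * self.score(query_row, include_self) > self.k)


def fit_atomic(
    train: ExpressionDataset,
    subset: FeatureSubset | Sequence[int],
    k: int,
    metric: str = "euclidean",
) -> AtomicClassifier:
    """Fit one atomic kNN classifier on a labeled training set."""
    if not isinstance(subset, FeatureSubset):
        subset = FeatureSubset(tuple(subset))
    if train.labels is None:
        raise ValueError("training set must be labeled")
    pool = AtomicPool([subset], k, metric, train.values, train.labels)
    return pool[0]


def fit_atomic_pool(
    train: ExpressionDataset,
    subsets: Sequence[FeatureSubset],
    k: int,
    metric: str = "euclidean",
) -> AtomicPool:
    """Fit a whole batch of atomic classifiers sharing the training set."""
    if train.labels is None:
        raise ValueError("training set must be labeled")
    return AtomicPool(
        subsets, k, metric, train.values, train.labels,
        feature_ids=list(train.feature_ids),
    )


def atomic_classify(
    ac: AtomicClassifier, query_row: np.ndarray, include_self: bool = True
) -> int:
    """Functional alias for :meth:`AtomicClassifier.classify`."""
    return ac.classify(query_row, include_self=include_self)


def knn_score(
    ac: AtomicClassifier, query_row: np.ndarray, include_self: bool = True
) -> int:
    """Functional alias for :meth:`AtomicClassifier.score`."""
    return ac.score(query_row, include_self=include_self)
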