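"""Comparison classifiers sharing the DRC split realizations.

The comparators are a Random Forest assembled from the *same*
class-stratified train/test realizations (one CART tree per realization,
bags drawn without resampling — stratified bags give reliable out-of-bag
estimates at small N), single and bagged kNN (with the neighbor-count
score for ROC construction), and single and bagged logistic regression,
optionally preceded by Welch t-test feature selection.

The tree learner itself is scikit-learn's CART (Gini, grown to purity);
everything around it — the stratified no-resampling bags, the
sample-count-based mtry rule, and the out-of-bag bookkeeping — is specific
to this framework.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from . import _knn
from .combiner import _sigmoid, fit_logistic
from .data_model import ExpressionDataset
from .ensemble import SplitRealization

__all__ = [
    "BaselineConfig",
    "ttest_select",
    "SingleKNN",
    "SingleLogistic",
    "BaggedModel",
    "RandomForestModel",
    "rf_train",
    "rf_score",
    "single_baseline",
    "bagged_baseline",
]

logger = logging.getLogger(__name__)


@dataclass
class BaselineConfig:
    """Parameters shared by the comparison methods."""

    method: str = "knn"
    n_features_selected: Optional[int] = None
    k: int = 7
    ridge_epsilon: float = 1e-6
    equal_var_ttest: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in (
            "rf", "knn", "knn_bagged", "logistic", "logistic_bagged"
        ):
            raise ValueError(f"unknown method {self.method!r}")
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be a positive odd integer")


def ttest_select(
    train: ExpressionDataset,
    n_keep: int,
    equal_var: bool = False,
) -> np.ndarray:
    """Features with the smallest two-sample t-test p-values.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled-variance variant). Ties are broken by feature order; the
    returned indices are in ascending feature order. A zero-variance
    feature gets p = 0 when the class means differ and p = 1 otherwise.
    """
    if train.labels is None:
        raise ValueError("training set must be labeled")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep > train.n_features:
        raise ValueError("n_keep exceeds number of features")
    X, y = train.values, train.labels
    g1, g0 = X[y == 1], X[y == 0]
    if g1.shape[0] < 2 or g0.shape[0] < 2:
        raise ValueError("both classes need at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features trigger a precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(g1, g0, axis=0, equal_var=equal_var)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        means_differ = ~np.isclose(g1.mean(axis=0), g0.mean(axis=0))
        pvals = np.where(degenerate, np.where(means_differ, 0.0, 1.0), pvals)
        logger.info(
            "%d zero-variance features handled in t-test selection",
            int(degenerate.sum()),
        )
    order = np.argsort(pvals, kind="stable")[:n_keep]
    return np.sort(order)


class SingleKNN:
    """kNN on the full (or t-test selected) feature set, neighbor-count score."""

    def __init__(
        self,
        train: ExpressionDataset,
        k: int,
        feature_indices: Optional[np.ndarray] = None,
    ):
        if train.labels is None:
            raise ValueError("training set must be labeled")
        if k > train.n_samples:
            raise ValueError("k exceeds training size")
        self.k = k
        self.feature_indices = (
            np.arange(train.n_features)
            if feature_indices is None
            else np.asarray(feature_indices, dtype=int)
        )
        self.refs = train.values[:, self.feature_indices]
        self.labels_mask = train.labels.astype(bool)

    def score(self, samples: Union[ExpressionDataset, np.ndarray]) -> np.ndarray:
        """Fraction of the k nearest training neighbors in class 1."""
        X = samples.values if isinstance(samples, ExpressionDataset) else samples
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.feature_indices]
        d = _knn.sq_dists(X, self.refs)
        votes = _knn.votes_from_dists(d, self.labels_mask, self.k)
        return votes / self.k


class SingleLogistic:
    """Ridge-safeguarded logistic regression on (selected) features."""

    def __init__(
        self,
        train: ExpressionDataset,
        ridge_epsilon: float = 1e-6,
        feature_indices: Optional[np.ndarray] = None,
    ):
        if train.labels is None:
            raise ValueError("training set must be labeled")
        self.feature_indices = (
            np.arange(train.n_features)
            if feature_indices is None
            else np.asarray(feature_indices, dtype=int)
        )
        design = train.values[:, self.feature_indices]
        self.weights, self.intercept = fit_logistic(
            design, train.labels, ridge_epsilon
        )

    def score(self, samples: Union[ExpressionDataset, np.ndarray]) -> np.ndarray:
        """Fitted class-1 probability."""
        X = samples.values if isinstance(samples, ExpressionDataset) else samples
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.feature_indices]
        return _sigmoid(self.intercept + X @ self.weights)


class BaggedModel:
    """Bag of per-realization learners with full and OOB scoring."""

    def __init__(
        self,
        learners: list,
        realizations: list[SplitRealization],
        n_dev: int,
    ):
        if len(learners) != len(realizations):
            raise ValueError("one learner per realization required")
        self.learners = learners
        self.realizations = realizations
        self.n_dev = n_dev

    def _outputs(self, samples) -> np.ndarray:
        return np.column_stack([ln.score(samples) for ln in self.learners])

    def score(self, samples, mode: str = "full") -> np.ndarray:
        """Mean of per-realization continuous outputs (full or OOB)."""
        outs = self._outputs(samples)
        if mode == "full":
            return outs.mean(axis=1)
        if mode != "oob":
            raise ValueError(f"unknown mode {mode!r}")
        if outs.shape[0] != self.n_dev:
            raise ValueError(
                f"oob scoring requires the full development set ({self.n_dev})"
            )
        mask = np.zeros((self.n_dev, len(self.learners)), dtype=bool)
        for j, r in enumerate(self.realizations):
            mask[r.test_indices, j] = True
        counts = mask.sum(axis=1)
        if (counts == 0).any():
            raise ValueError("some samples never appear in a test set")
        return (outs * mask).sum(axis=1) / counts


class RandomForestModel(BaggedModel):
    """Stratified-bag Random Forest: one CART tree per split realization."""

    def __init__(self, trees, realizations, n_dev, mtry):
        super().__init__(trees, realizations, n_dev)
        self.mtry = mtry

    def _outputs(self, samples) -> np.ndarray:
        X = samples.values if isinstance(samples, ExpressionDataset) else samples
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [t.predict(X).astype(float) for t in self.learners]
        )


def _mtry_rule(n_train: int, min_dev_class: int, p: int) -> int:
    """Features drawn per node: round(sqrt(N_train)), or round(N_train/3)
    when the development set has <= 30 samples per class (<= 20 per class
    in training)."""
    if min_dev_class <= 30:
        mtry = int(round(n_train / 3.0))
    else:
        mtry = int(round(np.sqrt(n_train)))
    mtry = max(1, mtry)
    if mtry > p:
        warnings.warn(f"mtry={mtry} exceeds feature count {p}; clamping")
        mtry = p
    return mtry


def rf_train(
    dev: ExpressionDataset,
    realizations: list[SplitRealization],
    rng_seed: int = 0,
) -> RandomForestModel:
    """Random Forest over the shared split realizations.

    Each tree is standard CART (Gini, grown to purity, no pruning) trained
    on one realization's training bag, drawing mtry candidate features per
    node. The continuous forest output is the mean of 0/1 tree votes; OOB
    output averages only trees whose realization holds the sample in test.
    """
    if dev.labels is None:
        raise ValueError("development set must be labeled")
    n_class = np.bincount(dev.labels, minlength=2)
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(realizations))
    trees = []
    mtry = None
    for r, child in zip(realizations, children):
        n_train = r.train_indices.size
        mtry = _mtry_rule(n_train, int(n_class.min()), dev.n_features)
        t = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(child.generate_state(1, dtype=np.uint32)[0]),
        )
        t.fit(dev.values[r.train_indices], dev.labels[r.train_indices])
        trees.append(t)
    return RandomForestModel(trees, list(realizations), dev.n_samples, mtry)


def rf_score(
    model: RandomForestModel,
    sample: np.ndarray,
    mode: str = "full",
    sample_index: Optional[int] = None,
) -> float:
    """Forest output for one sample (mean 0/1 tree vote, full or OOB)."""
    row = np.atleast_2d(np.asarray(sample, dtype=float))
    outs = model._outputs(row)[0]
    if mode == "full":
        return float(outs.mean())
    if mode != "oob":
        raise ValueError(f"unknown mode {mode!r}")
    if sample_index is None:
        raise ValueError("oob mode requires sample_index")
    sel = np.array(
        [sample_index in r.test_indices for r in model.realizations]
    )
    if not sel.any():
        raise ValueError(f"sample {sample_index} never appears in a test set")
    return float(outs[sel].mean())


def single_baseline(
    train: ExpressionDataset,
    learner: str,
    cfg: BaselineConfig,
) -> Union[SingleKNN, SingleLogistic]:
    """Fit a single (non-bagged) kNN or logistic classifier.

    Feature selection, when requested, uses the whole training set; the
    development-set assessment of single learners is resubstitution and
    correspondingly optimistic.
    """
    sel = None
    if cfg.n_features_selected is not None:
        sel = ttest_select(
            train, cfg.n_features_selected, equal_var=cfg.equal_var_ttest
        )
    if learner == "knn_score":
        return SingleKNN(train, cfg.k, feature_indices=sel)
    if learner == "logistic":
        return SingleLogistic(
            train, ridge_epsilon=cfg.ridge_epsilon, feature_indices=sel
        )
    raise ValueError(f"unknown learner {learner!r}")


def bagged_baseline(
    dev: ExpressionDataset,
    realizations: list[SplitRealization],
    learner: str,
    cfg: BaselineConfig,
) -> BaggedModel:
    """Bagged kNN or logistic regression over the shared realizations.

    Feature selection, when requested, is recomputed inside each bag's
    training set (no selection leakage into the out-of-bag samples).
    """
    if dev.labels is None:
        raise ValueError("development set must be labeled")
    learners = []
    for i, r in enumerate(realizations):
        bag = dev.take_samples(r.train_indices)
        try:
            learners.append(single_baseline(bag, learner, cfg))
        except RuntimeError as exc:
            raise RuntimeError(f"realization {i}: {exc}") from exc
    return BaggedModel(learners, list(realizations), dev.n_samples)
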