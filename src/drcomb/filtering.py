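"""Boosting-style admission of atomic classifiers.

Atomic classifiers are kept for combination only when they demonstrate a
minimal level of classification power on their own training set
(training accuracy within configured bounds; the lower bound is strict,
the upper inclusive). Because the accuracy is measured on the training set
itself it is over-optimistic — the bounds are therefore admission gates,
not performance estimates.

An optional *external filtering set* adds a second gate: the fraction of
external (unlabeled, unusable-for-training) samples a classifier assigns
to the class of interest must fall inside a configured band. This is the
confounder-mitigation mechanism — atomic classifiers that have learned a
confounder rather than the endpoint classify a carefully chosen external
cohort lopsidedly and are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .atomic import AtomicClassifier, AtomicPool
from .data_model import ExpressionDataset

__all__ = [
    "ExternalFilter",
    "FilterSpec",
    "FilterResult",
    "training_accuracy",
    "external_proportion",
    "filter_atomics",
    "accuracy_threshold_for_pass_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class ExternalFilter:
    """External-set constraint on the classified class-of-interest fraction."""

    dataset: ExpressionDataset
    class_of_interest: int = 1
    proportion_lower: float = 0.0
    proportion_upper: float = 1.0

    def __post_init__(self) -> None:
        if self.dataset.n_samples == 0:
            raise ValueError("external filtering set is empty")
        if self.class_of_interest not in (0, 1):
            raise ValueError("class_of_interest must be 0 or 1")
        if not 0.0 <= self.proportion_lower <= self.proportion_upper <= 1.0:
            raise ValueError("need 0 <= proportion_lower <= proportion_upper <= 1")


@dataclass
class FilterSpec:
    """Admission bounds for atomic classifiers.

    A classifier passes iff accuracy_lower < training accuracy <=
    accuracy_upper, and, when an external constraint is present,
    proportion_lower <= external class-of-interest fraction <=
    proportion_upper.
    """

    accuracy_lower: float = 0.0
    accuracy_upper: float = 1.0
    external: Optional[ExternalFilter] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_lower <= self.accuracy_upper <= 1.0:
            raise ValueError("need 0 <= accuracy_lower <= accuracy_upper <= 1")


@dataclass
class FilterResult:
    """Pool of survivors plus per-candidate diagnostics.

    ``train_outputs`` holds the passing classifiers' binary calls on the
    training set, shape (n_train, n_passing) — the design matrix the
    dropout combination consumes.
    """

    passing: AtomicPool
    pass_mask: np.ndarray
    accuracies: np.ndarray
    external_proportions: Optional[np.ndarray]
    train_outputs: Optional[np.ndarray] = None

    @property
    def pass_fraction(self) -> float:
        return float(self.pass_mask.mean()) if len(self.pass_mask) else 0.0


def training_accuracy(
    ac: AtomicClassifier,
    train: ExpressionDataset,
    include_self: bool = True,
) -> float:
    """Fraction of training samples the classifier calls correctly.

    With include_self=True (the default used during filtering) each
    training sample participates in its own neighborhood, so the value is
    over-optimistic by construction; it is used only as an admission gate.
    """
    if train.labels is None:
        raise ValueError("training set must be labeled")
    correct = sum(
        ac.classify(train.values[i], include_self=include_self)
        == train.labels[i]
        for i in range(train.n_samples)
    )
    return correct / train.n_samples


def external_proportion(
    ac: AtomicClassifier,
    external: ExpressionDataset,
    class_of_interest: int = 1,
) -> float:
    """Fraction of external samples classified as the class of interest."""
    if external.n_samples == 0:
        raise ValueError("external set is empty")
    calls = np.array(
        [ac.classify(external.values[i]) for i in range(external.n_samples)]
    )
    return float((calls == class_of_interest).mean())


def pool_training_accuracies(
    pool: AtomicPool, include_self: bool = True
) -> np.ndarray:
    """Training accuracy of every classifier in the pool (vectorized)."""
    preds = pool.training_classifications(include_self=include_self)
    return (preds == pool.train_labels[None, :]).mean(axis=1)


def pool_external_proportions(
    pool: AtomicPool, external: ExpressionDataset, class_of_interest: int = 1
) -> np.ndarray:
    """External class-of-interest fraction per classifier (vectorized)."""
    if external.n_samples == 0:
        raise ValueError("external set is empty")
    preds = pool.classify(external.values)
    return (preds == class_of_interest).mean(axis=1)


def accuracy_threshold_for_pass_fraction(
    accuracies: np.ndarray, target_fraction: float
) -> float:
    """Accuracy lower bound admitting roughly the requested fraction.

    Returns the (1 - target)-quantile of the candidate accuracy
    distribution, to be used as a strict lower bound. With heavily tied
    accuracies (they are multiples of 1/n_train) the realized pass
    fraction can deviate from the target; this mirrors choosing a fixed
    threshold so that "around" the target fraction passes. The bound is
    lowered when the quantile coincides with the maximum accuracy, so the
    pass set is never empty.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("no accuracies supplied")
    if target_fraction == 1.0:
        return -np.inf
    thr = float(np.quantile(acc, 1.0 - target_fraction))
    if not (acc > thr).any():
        below = acc[acc < acc.max()]
        thr = (
            float(below.max())
            if below.size
            else float(np.nextafter(acc.max(), -np.inf))
        )
    return thr


def filter_atomics(
    candidates: Union[AtomicPool, Sequence[AtomicClassifier]],
    train: ExpressionDataset,
    spec: FilterSpec,
    include_self: bool = True,
    _train_preds: Optional[np.ndarray] = None,
) -> FilterResult:
    """Apply the admission gates to a pool of candidate atomic classifiers.

    Candidate order is preserved. Raises when no classifier survives —
    the downstream logistic combination is undefined on an empty pool and
    the caller should widen the bounds. ``_train_preds`` may carry the
    precomputed (n_candidates, n_train) training classification matrix to
    avoid recomputation inside pipelines.
    """
    if isinstance(candidates, AtomicPool):
        pool = candidates
    else:
        cands = list(candidates)
        if not cands:
            raise ValueError("no candidate atomic classifiers")
        if train.labels is None:
            raise ValueError("training set must be labeled")
        pool = AtomicPool(
            [ac.subset for ac in cands],
            cands[0].k,
            cands[0].metric,
            train.values,
            train.labels,
        )
    if _train_preds is None:
        _train_preds = pool.training_classifications(include_self=include_self)
    accs = (_train_preds == pool.train_labels[None, :]).mean(axis=1)
    mask = (accs > spec.accuracy_lower) & (accs <= spec.accuracy_upper)
    props: Optional[np.ndarray] = None
    if spec.external is not None:
        ext = spec.external
        props = pool_external_proportions(
            pool, ext.dataset, ext.class_of_interest
        )
        mask &= (props >= ext.proportion_lower) & (props <= ext.proportion_upper)
    if not mask.any():
        raise ValueError(
            "no atomic classifier passed filtering; widen the accuracy "
            "or external-proportion bounds"
        )
    logger.info(
        "filtering: %d/%d atomic classifiers passed (%.1f%%)",
        int(mask.sum()), len(mask), 100.0 * mask.mean(),
    )
    return FilterResult(
        passing=pool.select(mask),
        pass_mask=mask,
        accuracies=accs,
        external_proportions=props,
        train_outputs=_train_preds[mask].T.astype(np.int8),
    )
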