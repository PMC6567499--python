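"""Dropout-regularized logistic combination of filtered atomic classifiers.

The binary outputs of the atomic classifiers that passed filtering are
combined into a single continuous score by logistic regression. Because
very many atomic classifiers survive filtering, the regression is strongly
regularized with a dropout scheme: at each iteration a small number *d* of
atomic classifiers is drawn at random (without replacement), a logistic
regression is fitted on just those columns, and the fitted coefficients
are accumulated. The final weight of an atomic classifier is its
accumulated coefficient divided by the total number of iterations (a
classifier contributes zero in iterations where it was not drawn), which
shrinks all weights toward zero — dropout applied to logistic regression
is first-order equivalent to an L2 penalty.

The logistic fits themselves use a damped Newton solver with a tiny ridge
``ridge_epsilon`` on the non-intercept weights as a perfect-separation
safeguard (separation is routine when d columns are fitted on a small
balanced training set). The solver is batched: hundreds of tiny
regressions are advanced simultaneously, which is what makes 1e5 dropout
iterations affordable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .atomic import AtomicClassifier, AtomicPool
from .data_model import ExpressionDataset

__all__ = [
    "DropoutConfig",
    "BaseClassifier",
    "atomic_output_matrix",
    "fit_logistic",
    "dropout_combine",
    "base_apply",
]

logger = logging.getLogger(__name__)

_DRAW_BATCH = 512


@dataclass
class DropoutConfig:
    """Dropout-regularization parameters.

    d : atomic classifiers drawn per iteration; should be smaller than the
        training-set size (d=10 works in most settings with thousands of
        passing atomic classifiers — use smaller d for small pools).
    n_iterations : dropout iterations; choose so each atomic classifier is
        drawn multiple times (typically 10-100) when the pool allows it.
    ridge_epsilon : L2 strength on non-intercept weights
        (separation safeguard).
    average_over : "iterations" divides accumulated weights by the total
        iteration count (default); "draws" divides each weight by its own
        selection count instead.
    """

    d: int = 10
    n_iterations: int = 100_000
    ridge_epsilon: float = 1e-6
    rng_seed: int = 0
    average_over: str = "iterations"

    def __post_init__(self) -> None:
        if self.d < 1 or self.n_iterations < 1:
            raise ValueError("d and n_iterations must be positive")
        if self.ridge_epsilon < 0:
            raise ValueError("ridge_epsilon must be non-negative")
        if self.average_over not in ("iterations", "draws"):
            raise ValueError("average_over must be 'iterations' or 'draws'")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _penalized_deviance(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, eps: float
) -> np.ndarray:
    """Objective per batch element: -loglik + 0.5*eps*||w||^2."""
    eta = (X @ beta[..., None])[..., 0]
    ll = np.logaddexp(0.0, eta) - y * eta
    pen = 0.5 * eps * (beta[:, 1:] ** 2).sum(axis=1)
    return ll.sum(axis=1) + pen


def _newton_logistic_batch(
    X: np.ndarray,
    y: np.ndarray,
    eps: float,
    max_iter: int = 200,
    gtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped-Newton ridge-logistic fits for a batch of design matrices.

    X has shape (B, n, q) with the intercept as column 0 (unpenalized).
    Returns (beta of shape (B, q), converged bool mask of shape (B,)).
    """
    B, n, q = X.shape
    y = np.broadcast_to(np.asarray(y, dtype=float), (B, n))
    beta = np.zeros((B, q))
    pen = np.ones(q)
    pen[0] = 0.0
    jitter = 1e-10
    converged = np.zeros(B, dtype=bool)
    # active-set compaction: elements leave the working set as they converge
    active = np.arange(B)
    Xa = X
    Xta = np.ascontiguousarray(X.transpose(0, 2, 1))
    ya = y
    beta_a = beta[active]
    f_a = _penalized_deviance(Xa, ya, beta_a, eps)
    diag = np.diag(eps * pen + jitter)
    for _ in range(max_iter):
        eta = (Xa @ beta_a[..., None])[..., 0]
        mu = _sigmoid(eta)
        g = (Xta @ (mu - ya)[..., None])[..., 0] + eps * pen * beta_a
        done = np.abs(g).max(axis=1) <= gtol
        if done.any():
            converged[active[done]] = True
            beta[active[done]] = beta_a[done]
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            Xa, Xta, ya = Xa[keep], Xta[keep], ya[keep]
            beta_a, f_a, g, mu = beta_a[keep], f_a[keep], g[keep], mu[keep]
        w = mu * (1.0 - mu)
        H = Xta @ (Xa * w[..., None])
        H += diag
        step = np.linalg.solve(H, g[..., None])[..., 0]
        t = np.ones(active.size)
        trial = beta_a - step
        f_try = _penalized_deviance(Xa, ya, trial, eps)
        worse = f_try > f_a + 1e-12
        for _ in range(40):
            if not worse.any():
                break
            t[worse] *= 0.5
            sub = np.flatnonzero(worse)
            trial[sub] = beta_a[sub] - t[sub, None] * step[sub]
            f_try[sub] = _penalized_deviance(Xa[sub], ya[sub], trial[sub], eps)
            worse[sub] = f_try[sub] > f_a[sub] + 1e-12
        beta_a, f_a = trial, f_try
    beta[active] = beta_a if active.size else beta[active]
    return beta, converged


def fit_logistic(
    design: np.ndarray,
    labels: np.ndarray,
    ridge_epsilon: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, float]:
    """Fit one logistic regression with ridge on non-intercept weights.

    Returns (weights, intercept). Deterministic for fixed inputs; raises
    on non-convergence after ``max_iter`` Newton iterations.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("design must be 2-D with >= 1 column")
    y = np.asarray(labels, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("labels length must match design rows")
    Xi = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    beta, conv = _newton_logistic_batch(
        Xi[None, :, :], y, ridge_epsilon, max_iter=max_iter
    )
    if not conv[0]:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} Newton iterations "
            f"(n={X.shape[0]}, q={X.shape[1]}, ridge={ridge_epsilon}); "
            "the design may be degenerate"
        )
    return beta[0, 1:].copy(), float(beta[0, 0])


def atomic_output_matrix(
    atomics: Union[AtomicPool, Sequence[AtomicClassifier]],
    samples: Union[ExpressionDataset, np.ndarray],
) -> np.ndarray:
    """Binary 0/1 classification matrix, shape (n_samples, n_atomics)."""
    X = samples.values if isinstance(samples, ExpressionDataset) else samples
    if isinstance(atomics, AtomicPool):
        return atomics.classify(X).T.astype(np.int8)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], len(atomics)), dtype=np.int8)
    for j, ac in enumerate(atomics):
        for i in range(X.shape[0]):
            out[i, j] = ac.classify(X[i])
    return out


@dataclass
class BaseClassifier:
    """Dropout-averaged logistic combination for one split realization.

    ``atomics`` is the pool of passing atomic classifiers; ``weights`` is
    aligned to it (exactly zero for classifiers never drawn). The output
    of :meth:`apply` is logistic(intercept + weights . atomic outputs),
    strictly inside (0, 1).
    """

    atomics: AtomicPool
    weights: np.ndarray
    intercept: float
    selection_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.atomics):
            raise ValueError("weights length must equal number of atomics")
        if self.selection_counts is None:
            self.selection_counts = np.zeros(len(self.weights), dtype=int)

    def apply_outputs(self, outputs: np.ndarray) -> np.ndarray:
        """Score samples given their precomputed atomic output matrix."""
        eta = self.intercept + outputs.astype(float) @ self.weights
        return _sigmoid(np.atleast_1d(eta))

    def apply(self, samples: Union[ExpressionDataset, np.ndarray]) -> np.ndarray:
        """Continuous scores in (0,1) for raw sample rows."""
        outputs = atomic_output_matrix(self.atomics, samples)
        return self.apply_outputs(outputs)


def base_apply(bc: BaseClassifier, sample: np.ndarray) -> float:
    """Continuous score in (0, 1) for a single sample row."""
    return float(bc.apply(np.atleast_2d(np.asarray(sample, dtype=float)))[0])


def dropout_combine(
    passing: Union[AtomicPool, Sequence[AtomicClassifier]],
    train: ExpressionDataset,
    cfg: DropoutConfig,
    outputs: Optional[np.ndarray] = None,
) -> BaseClassifier:
    """Combine passing atomic classifiers by dropout-averaged logistic fits.

    For each of ``cfg.n_iterations`` iterations, ``cfg.d`` distinct atomic
    classifiers are drawn uniformly without replacement, a ridge-logistic
    regression of the training labels on their binary outputs is fitted,
    and the coefficients are accumulated. Weights are averaged over all
    iterations (never-drawn classifiers keep weight 0); the intercept is
    the mean over iterations. Reproducible given ``cfg.rng_seed``.

    ``outputs`` may supply the precomputed (n_train, n_passing) atomic
    output matrix to avoid recomputation.
    """
    if not isinstance(passing, AtomicPool):
        if len(passing) == 0:
            raise ValueError("passing pool is empty")
        if train.labels is None:
            raise ValueError("training set must be labeled")
        passing = AtomicPool(
            [ac.subset for ac in passing],
            passing[0].k,
            passing[0].metric,
            train.values,
            train.labels,
        )
    P = len(passing)
    if P == 0:
        raise ValueError("passing pool is empty")
    y = train.labels
    if y is None:
        raise ValueError("training set must be labeled")
    n = train.n_samples
    d = cfg.d
    if d > P:
        warnings.warn(
            f"dropout draw size d={d} exceeds pool size {P}; clamping to {P}"
        )
        d = P
    if d >= n:
        warnings.warn(
            f"dropout draw size d={d} is not smaller than the training-set "
            f"size {n}; regularization may be ineffective"
        )
    if outputs is None:
        outputs = atomic_output_matrix(passing, train)
    outputs = np.asarray(outputs)
    if outputs.shape != (n, P):
        raise ValueError("outputs shape must be (n_train, n_passing)")

    rng = np.random.default_rng(cfg.rng_seed)
    weight_sums = np.zeros(P)
    counts = np.zeros(P, dtype=np.int64)
    intercept_sum = 0.0
    out_f = outputs.astype(float)
    remaining = cfg.n_iterations
    while remaining > 0:
        B = min(_DRAW_BATCH, remaining)
        remaining -= B
        if d == P:
            draws = np.broadcast_to(np.arange(P), (B, P)).copy()
        else:
            keys = rng.random((B, P))
            draws = np.argpartition(keys, d - 1, axis=1)[:, :d]
        cols = out_f[:, draws]                      # (n, B, d)
        X = np.empty((B, n, d + 1))
        X[:, :, 0] = 1.0
        X[:, :, 1:] = np.moveaxis(cols, 1, 0)
        beta, conv = _newton_logistic_batch(X, y.astype(float), cfg.ridge_epsilon)
        if not conv.all():
            bad = int(np.flatnonzero(~conv)[0])
            raise RuntimeError(
                "dropout iteration failed to converge "
                f"(batch element {bad}, d={d}, n={n})"
            )
        np.add.at(weight_sums, draws.ravel(), beta[:, 1:].ravel())
        np.add.at(counts, draws.ravel(), 1)
        intercept_sum += beta[:, 0].sum()

    if cfg.average_over == "iterations":
        weights = weight_sums / cfg.n_iterations
    else:
        weights = np.where(counts > 0, weight_sums / np.maximum(counts, 1), 0.0)
    intercept = intercept_sum / cfg.n_iterations
    logger.info(
        "dropout_combine: pool=%d, d=%d, iterations=%d, "
        "min/median/max draws per classifier = %d/%d/%d",
        P, d, cfg.n_iterations,
        int(counts.min()), int(np.median(counts)), int(counts.max()),
    )
    return BaseClassifier(
        atomics=passing,
        weights=weights,
        intercept=intercept,
        selection_counts=counts,
    )
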