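"""Bagged ensemble of dropout-combined base classifiers.

The development set is split many times into class-stratified training and
test portions ("split realizations"; equal class counts in training to
avoid bias in the logistic combination). One base classifier is trained
per realization (atomic fits -> filtering -> dropout combination), and the
*master classifier* is the bag: its continuous output for a sample is the
mean of the base outputs.

For samples that belong to the development set, the *out-of-bag* (OOB)
score averages only the bases from realizations in which the sample sat in
the test portion — the sample never influenced those bases — yielding an
honest development-set performance estimate. At the default 325
realizations with a 2:1 train:test split, every sample lands in the test
portion well over 100 times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .atomic import (
    AtomicPool,
    FeatureSubset,
    enumerate_restricted_pairs,
    enumerate_subsets,
)
from .combiner import BaseClassifier, DropoutConfig, dropout_combine
from .data_model import ExpressionDataset
from .filtering import (
    ExternalFilter,
    FilterSpec,
    accuracy_threshold_for_pass_fraction,
    filter_atomics,
)

__all__ = [
    "SplitRealization",
    "DRCConfig",
    "MasterClassifier",
    "generate_realizations",
    "train_master",
    "master_score",
    "classify",
    "select_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitRealization:
    """One class-stratified split of the development set."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test indices overlap")


@dataclass
class DRCConfig:
    """Full configuration of a dropout-regularized combination classifier.

    Defaults are the production-scale settings: 325 realizations with 2/3
    of samples used for training, kNN atomic classifiers with k=7 and
    Euclidean distance on all singles and pairs, filtering tuned so that
    around 25% of atomic classifiers pass, and 100,000 dropout iterations
    drawing d=10 atomic classifiers each. Tests and examples pass
    explicitly scaled-down values.
    """

    n_realizations: int = 325
    train_fraction: float = 2.0 / 3.0
    k: int = 7
    metric: str = "euclidean"
    max_order: int = 2
    hierarchical: bool = False
    include_self: bool = True
    accuracy_lower: Optional[float] = None
    accuracy_upper: float = 1.0
    pass_fraction: float = 0.25
    external: Optional[ExternalFilter] = None
    dropout_d: int = 10
    dropout_iterations: int = 100_000
    ridge_epsilon: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be positive")
        if self.hierarchical and self.max_order < 2:
            raise ValueError("hierarchical mode requires max_order >= 2")


def generate_realizations(
    labels: np.ndarray,
    n_realizations: int,
    train_fraction: float = 2.0 / 3.0,
    rng_seed: int = 0,
) -> list[SplitRealization]:
    """Draw class-stratified train/test split realizations.

    Each realization puts floor(train_fraction * N / 2) samples of *each*
    class into training (capped at class size - 1 for unbalanced sets, so
    the majority class is undersampled); all remaining samples form the
    test portion. Reproducible given ``rng_seed``.
    """
    y = np.asarray(labels, dtype=int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be non-empty")
    n_per_class = int(np.floor(train_fraction * y.size / 2.0))
    cap = min(idx0.size, idx1.size) - 1
    if n_per_class > cap:
        warnings.warn(
            f"per-class training count {n_per_class} capped at {cap} "
            "(smallest class must keep at least one test sample)"
        )
        n_per_class = cap
    if n_per_class < 1:
        raise ValueError(
            "per-class training count is below 1; increase the sample size "
            "or the training fraction"
        )
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_realizations):
        tr0 = rng.choice(idx0, size=n_per_class, replace=False)
        tr1 = rng.choice(idx1, size=n_per_class, replace=False)
        train = np.sort(np.concatenate([tr0, tr1]))
        test = np.setdiff1d(np.arange(y.size), train)
        out.append(SplitRealization(train_indices=train, test_indices=test))
    return out


@dataclass
class MasterClassifier:
    """Bag of base classifiers over split realizations."""

    realizations: list[SplitRealization]
    bases: list[BaseClassifier]
    config: DRCConfig
    n_dev: int
    dev_sample_ids: Optional[list[str]] = None
    pass_fractions: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.realizations):
            raise ValueError("one base classifier per realization required")

    # -- scoring -------------------------------------------------------
    def base_outputs(self, samples) -> np.ndarray:
        """Matrix of base-classifier outputs, shape (n_samples, n_bases)."""
        X = samples.values if isinstance(samples, ExpressionDataset) else samples
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([bc.apply(X) for bc in self.bases])

    def score(self, samples, mode: str = "full") -> np.ndarray:
        """Ensemble-average continuous scores in (0, 1).

        mode="full" averages all bases. mode="oob" requires ``samples`` to
        be the full development set (same sample order as during training)
        and averages, per sample, only bases whose realization held that
        sample in the test portion.
        """
        outs = self.base_outputs(samples)
        if mode == "full":
            return outs.mean(axis=1)
        if mode != "oob":
            raise ValueError(f"unknown mode {mode!r}")
        if outs.shape[0] != self.n_dev:
            raise ValueError(
                "oob scoring requires the full development set "
                f"({self.n_dev} samples, got {outs.shape[0]})"
            )
        mask = self.test_membership_matrix()  # (n_dev, n_bases)
        counts = mask.sum(axis=1)
        if (counts == 0).any():
            missing = np.flatnonzero(counts == 0)
            raise ValueError(
                f"samples {missing.tolist()} never appear in any test set; "
                "increase n_realizations"
            )
        return (outs * mask).sum(axis=1) / counts

    def test_membership_matrix(self) -> np.ndarray:
        """Boolean (n_dev, n_bases): sample in realization's test portion."""
        m = np.zeros((self.n_dev, len(self.bases)), dtype=bool)
        for j, r in enumerate(self.realizations):
            m[r.test_indices, j] = True
        return m

    def membership_digest(self) -> str:
        """Hash of all realization memberships (for cross-method audits)."""
        h = hashlib.sha256()
        for r in self.realizations:
            h.update(r.train_indices.tobytes())
            h.update(r.test_indices.tobytes())
        return h.hexdigest()

    # -- serialization -------------------------------------------------
    def save(self, directory: str | os.PathLike) -> None:
        """Serialize config, realization memberships and base weights."""
        os.makedirs(directory, exist_ok=True)
        cfg = dataclasses.asdict(self.config)
        cfg.pop("external", None)
        cfg["has_external_filter"] = self.config.external is not None
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(
                {
                    "config": cfg,
                    "n_dev": self.n_dev,
                    "dev_sample_ids": self.dev_sample_ids,
                    "pass_fractions": self.pass_fractions,
                },
                fh,
                indent=1,
            )
        lines = ["realization,train_indices,test_indices"]
        for i, r in enumerate(self.realizations):
            lines.append(
                f"{i},{' '.join(map(str, r.train_indices))},"
                f"{' '.join(map(str, r.test_indices))}"
            )
        with open(os.path.join(directory, "realizations.csv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
        bdir = os.path.join(directory, "bases")
        os.makedirs(bdir, exist_ok=True)
        for i, bc in enumerate(self.bases):
            ref_digest = hashlib.sha256(
                bc.atomics.raw_train.tobytes()
            ).hexdigest()
            payload = {
                "subsets": [list(s.indices) for s in bc.atomics.subsets],
                "k": bc.atomics.k,
                "metric": bc.atomics.metric,
                "weights": bc.weights.tolist(),
                "intercept": bc.intercept,
                "selection_counts": bc.selection_counts.tolist(),
                "reference_digest": ref_digest,
            }
            with open(os.path.join(bdir, f"base_{i:04d}.json"), "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def load(
        cls, directory: str | os.PathLike, dev: ExpressionDataset
    ) -> "MasterClassifier":
        """Rebuild a saved master from its directory plus the dev dataset."""
        with open(os.path.join(directory, "config.json")) as fh:
            meta = json.load(fh)
        cfgd = dict(meta["config"])
        cfgd.pop("has_external_filter", None)
        config = DRCConfig(**cfgd)
        realizations = []
        with open(os.path.join(directory, "realizations.csv")) as fh:
            next(fh)
            for line in fh:
                _, tr, te = line.rstrip("\n").split(",")
                realizations.append(
                    SplitRealization(
                        np.array(tr.split(), dtype=int),
                        np.array(te.split(), dtype=int),
                    )
                )
        bases = []
        bdir = os.path.join(directory, "bases")
        for i, r in enumerate(realizations):
            with open(os.path.join(bdir, f"base_{i:04d}.json")) as fh:
                payload = json.load(fh)
            train = dev.take_samples(r.train_indices)
            pool = AtomicPool(
                [FeatureSubset(tuple(s)) for s in payload["subsets"]],
                payload["k"],
                payload["metric"],
                train.values,
                train.labels,
            )
            digest = hashlib.sha256(pool.raw_train.tobytes()).hexdigest()
            if digest != payload["reference_digest"]:
                raise ValueError(
                    f"base {i}: development data do not match the "
                    "serialized reference digest"
                )
            bases.append(
                BaseClassifier(
                    atomics=pool,
                    weights=np.array(payload["weights"]),
                    intercept=payload["intercept"],
                    selection_counts=np.array(
                        payload["selection_counts"], dtype=int
                    ),
                )
            )
        return cls(
            realizations=realizations,
            bases=bases,
            config=config,
            n_dev=meta["n_dev"],
            dev_sample_ids=meta.get("dev_sample_ids"),
            pass_fractions=meta.get("pass_fractions"),
        )


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def train_master(
    dev: ExpressionDataset,
    config: DRCConfig,
) -> MasterClassifier:
    """Train the full hierarchy on a labeled development set.

    Per realization: fit all candidate atomic classifiers on the training
    portion, filter them (by training accuracy, plus the external-set
    constraint if configured), combine survivors with dropout-regularized
    logistic regression. Candidate subsets are enumerated once; in
    hierarchical mode the restricted pair list is recomputed per
    realization from that realization's passing single features.

    Deterministic given ``config.rng_seed`` (per-realization dropout
    streams are spawned from the master seed).
    """
    if dev.labels is None:
        raise ValueError("development set must be labeled")
    p = dev.n_features
    ss = np.random.SeedSequence(config.rng_seed)
    split_ss, drop_ss = ss.spawn(2)
    realizations = generate_realizations(
        dev.labels,
        config.n_realizations,
        config.train_fraction,
        rng_seed=_child_seed(split_ss),
    )
    in_test = np.zeros(dev.n_samples, dtype=int)
    for r in realizations:
        in_test[r.test_indices] += 1
    if (in_test == 0).any():
        warnings.warn(
            f"{int((in_test == 0).sum())} development samples never appear "
            "in a test set; OOB scores for them are undefined"
        )

    if config.hierarchical:
        singles = enumerate_subsets(p, 1)
        candidates = None
    else:
        candidates = enumerate_subsets(p, config.max_order)

    drop_children = drop_ss.spawn(config.n_realizations)
    bases: list[BaseClassifier] = []
    pass_fractions: list[float] = []
    for r_idx, real in enumerate(realizations):
        train = dev.take_samples(real.train_indices)
        try:
            if config.hierarchical:
                pool_s = AtomicPool(
                    singles, config.k, config.metric, train.values, train.labels
                )
                preds_s = pool_s.training_classifications(config.include_self)
                accs_s = (preds_s == pool_s.train_labels[None, :]).mean(axis=1)
                lower = (
                    config.accuracy_lower
                    if config.accuracy_lower is not None
                    else accuracy_threshold_for_pass_fraction(
                        accs_s, config.pass_fraction
                    )
                )
                spec = FilterSpec(
                    accuracy_lower=max(lower, 0.0),
                    accuracy_upper=config.accuracy_upper,
                    external=config.external,
                )
                res_s = filter_atomics(
                    pool_s, train, spec, config.include_self, _train_preds=preds_s
                )
                passing_feats = [
                    s.indices[0]
                    for s, ok in zip(singles, res_s.pass_mask)
                    if ok
                ]
                pairs = enumerate_restricted_pairs(passing_feats)
                if pairs:
                    pool_p = AtomicPool(
                        pairs, config.k, config.metric,
                        train.values, train.labels,
                    )
                    preds_p = pool_p.training_classifications(
                        config.include_self
                    )
                    if config.accuracy_lower is None:
                        # pass-fraction targeting is applied per candidate
                        # family: pairs fit their training set better than
                        # singles, so a singles-derived bound would admit
                        # nearly all pairs
                        accs_p = (
                            preds_p == pool_p.train_labels[None, :]
                        ).mean(axis=1)
                        spec_p = FilterSpec(
                            accuracy_lower=max(
                                accuracy_threshold_for_pass_fraction(
                                    accs_p, config.pass_fraction
                                ),
                                0.0,
                            ),
                            accuracy_upper=config.accuracy_upper,
                            external=config.external,
                        )
                    else:
                        spec_p = spec
                    try:
                        res_p = filter_atomics(
                            pool_p, train, spec_p, config.include_self,
                            _train_preds=preds_p,
                        )
                        passing_subsets = (
                            res_s.passing.subsets + res_p.passing.subsets
                        )
                        outputs = np.concatenate(
                            [res_s.train_outputs, res_p.train_outputs], axis=1
                        )
                    except ValueError:
                        # no pair survived; fall back to passing singles
                        passing_subsets = res_s.passing.subsets
                        outputs = res_s.train_outputs
                else:
                    passing_subsets = res_s.passing.subsets
                    outputs = res_s.train_outputs
                passing = AtomicPool(
                    passing_subsets, config.k, config.metric,
                    train.values, train.labels,
                )
                n_cand = len(singles) + len(pairs)
                frac = len(passing_subsets) / max(n_cand, 1)
            else:
                pool = AtomicPool(
                    candidates, config.k, config.metric,
                    train.values, train.labels,
                )
                preds = pool.training_classifications(config.include_self)
                accs = (preds == pool.train_labels[None, :]).mean(axis=1)
                lower = (
                    config.accuracy_lower
                    if config.accuracy_lower is not None
                    else accuracy_threshold_for_pass_fraction(
                        accs, config.pass_fraction
                    )
                )
                spec = FilterSpec(
                    accuracy_lower=max(lower, 0.0),
                    accuracy_upper=config.accuracy_upper,
                    external=config.external,
                )
                res = filter_atomics(
                    pool, train, spec, config.include_self, _train_preds=preds
                )
                passing = res.passing
                outputs = res.train_outputs
                frac = res.pass_fraction
        except ValueError as exc:
            raise ValueError(
                f"realization {r_idx}: {exc}"
            ) from exc
        dcfg = DropoutConfig(
            d=min(config.dropout_d, len(passing)),
            n_iterations=config.dropout_iterations,
            ridge_epsilon=config.ridge_epsilon,
            rng_seed=_child_seed(drop_children[r_idx]),
        )
        bc = dropout_combine(passing, train, dcfg, outputs=outputs)
        bases.append(bc)
        pass_fractions.append(frac)
        logger.info(
            "realization %d/%d: %d passing atomics (%.1f%%)",
            r_idx + 1, config.n_realizations, len(passing), 100 * frac,
        )
    return MasterClassifier(
        realizations=realizations,
        bases=bases,
        config=config,
        n_dev=dev.n_samples,
        dev_sample_ids=list(dev.sample_ids),
        pass_fractions=pass_fractions,
    )


def master_score(
    mc: MasterClassifier,
    sample: np.ndarray,
    mode: str = "full",
    sample_index: Optional[int] = None,
) -> float:
    """Ensemble-average score of one sample.

    mode="oob" requires ``sample_index`` — the sample's row index in the
    development set the master was trained on — and averages only bases
    from realizations holding that sample in the test portion.
    """
    row = np.atleast_2d(np.asarray(sample, dtype=float))
    outs = np.array([bc.apply(row)[0] for bc in mc.bases])
    if mode == "full":
        return float(outs.mean())
    if mode != "oob":
        raise ValueError(f"unknown mode {mode!r}")
    if sample_index is None:
        raise ValueError("oob mode requires sample_index")
    sel = np.array(
        [sample_index in r.test_indices for r in mc.realizations]
    )
    if not sel.any():
        raise ValueError(
            f"sample {sample_index} never appears in a test set"
        )
    return float(outs[sel].mean())


def classify(
    mc: MasterClassifier,
    sample: np.ndarray,
    threshold: float,
    mode: str = "full",
    sample_index: Optional[int] = None,
) -> int:
    """Binary call: 1 iff the master score reaches the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return int(master_score(mc, sample, mode, sample_index) >= threshold)


def select_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    rule: str = "youden",
    fixed: Optional[float] = None,
) -> float:
    """Choose the binary-classification threshold from development scores.

    rule="youden": the midpoint between consecutive distinct scores that
    maximizes TPR - FPR (classify 1 iff score >= threshold); among ties
    the lowest such threshold is returned. rule="fixed" passes ``fixed``
    through. With all scores identical Youden's J is uninformative and 0.5
    is returned with a warning.
    """
    if rule == "fixed":
        if fixed is None:
            raise ValueError("rule='fixed' requires a threshold value")
        return float(fixed)
    if rule != "youden":
        raise ValueError(f"unknown rule {rule!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to select a threshold")
    distinct = np.unique(s)
    if distinct.size == 1:
        warnings.warn("all scores identical; returning threshold 0.5")
        return 0.5
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best_j, best_t = -np.inf, mids[0]
    for t in mids:
        pred = s >= t
        j = (pred & (y == 1)).sum() / n1 - (pred & (y == 0)).sum() / n0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)
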