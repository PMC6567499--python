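"""ROC/AUC computation and development-set evaluation protocols.

AUC is computed as the exact Mann-Whitney probability (ties credited 0.5):
AUC = [#(s1 > s0) + 0.5 * #(s1 = s0)] / (n1 * n0), which is identical to
the trapezoidal area under the empirical ROC curve but free of binning
choices. The stored curve (from all distinct thresholds) is for plotting.

Development-set performance is reported three ways, mirroring how a bagged
classifier should be assessed: out-of-bag on the development subset,
standard classification on internal-validation samples (development
samples not used for classifier generation), and the pooled combination of
the two over the whole development cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data_model import ExpressionDataset
from .ensemble import DRCConfig, MasterClassifier, train_master

__all__ = [
    "RocResult",
    "SweepSummary",
    "roc_auc",
    "evaluate_development",
    "subset_size_sweep",
    "summarize_sweep",
]


@dataclass
class RocResult:
    """ROC curve plus the exact Mann-Whitney AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class SweepSummary:
    """Per-realization AUCs with mean and standard error (sample SD / sqrt n)."""

    aucs: np.ndarray
    mean: float
    se: Optional[float]

    @classmethod
    def from_aucs(cls, aucs: Sequence[float]) -> "SweepSummary":
        a = np.asarray(aucs, dtype=float)
        se = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size >= 2 else None
        return cls(aucs=a, mean=float(a.mean()), se=se)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Mann-Whitney AUC (ties credited 0.5) with the empirical ROC curve.

    Scores must be oriented so larger means more class-1-like.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have matching shapes")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def evaluate_development(
    mc: MasterClassifier,
    dev_subset: ExpressionDataset,
    internal_holdout: Optional[ExpressionDataset] = None,
) -> dict[str, Optional[RocResult]]:
    """OOB, internal-validation and combined ROC for a trained master.

    ``dev_subset`` must be the set the master was trained on;
    ``internal_holdout`` (possibly empty/None) holds labeled development
    samples disjoint from it, scored in full mode. The combined result
    pools the OOB scores with the holdout scores.
    """
    if dev_subset.labels is None:
        raise ValueError("development subset must be labeled")
    if internal_holdout is not None and internal_holdout.n_samples:
        overlap = set(dev_subset.sample_ids) & set(internal_holdout.sample_ids)
        if overlap:
            raise ValueError(
                f"{len(overlap)} samples appear in both the development "
                "subset and the internal holdout"
            )
    oob_scores = mc.score(dev_subset, mode="oob")
    out: dict[str, Optional[RocResult]] = {
        "oob": roc_auc(oob_scores, dev_subset.labels)
    }
    if internal_holdout is None or internal_holdout.n_samples == 0:
        out["int_val"] = None
        out["all"] = out["oob"]
        return out
    if internal_holdout.labels is None:
        raise ValueError("internal holdout must be labeled")
    hold_scores = mc.score(internal_holdout, mode="full")
    out["int_val"] = roc_auc(hold_scores, internal_holdout.labels)
    pooled_scores = np.concatenate([oob_scores, hold_scores])
    pooled_labels = np.concatenate(
        [dev_subset.labels, internal_holdout.labels]
    )
    out["all"] = roc_auc(pooled_scores, pooled_labels)
    return out


def subset_size_sweep(
    dev: ExpressionDataset,
    val: ExpressionDataset,
    sizes_per_class: Sequence[int],
    n_reps: int,
    config: DRCConfig,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Classifier performance as a function of development-subset size.

    For each size, ``n_reps`` balanced subsets are drawn from the
    development cohort, a master classifier is trained on each, and the
    AUC is recorded for four assessment modes: development-subset OOB,
    internal validation (development samples outside the subset), the
    whole development cohort (pooled), and the independent validation set.

    Returns a tidy frame with columns
    (size_per_class, realization, mode, auc).
    """
    if dev.labels is None or val.labels is None:
        raise ValueError("both datasets must be labeled")
    idx0 = np.flatnonzero(dev.labels == 0)
    idx1 = np.flatnonzero(dev.labels == 1)
    max_size = min(idx0.size, idx1.size)
    if max(sizes_per_class) > max_size:
        raise ValueError(
            f"requested size {max(sizes_per_class)}/class exceeds the "
            f"smallest class ({max_size})"
        )
    ss = np.random.SeedSequence(rng_seed)
    rows = []
    for size in sizes_per_class:
        for rep in range(n_reps):
            child = ss.spawn(1)[0]
            seeds = child.generate_state(2, dtype=np.uint32) % (2**31)
            rng = np.random.default_rng(int(seeds[0]))
            sub0 = rng.choice(idx0, size=size, replace=False)
            sub1 = rng.choice(idx1, size=size, replace=False)
            sub_idx = np.sort(np.concatenate([sub0, sub1]))
            rest_idx = np.setdiff1d(np.arange(dev.n_samples), sub_idx)
            subset = dev.take_samples(sub_idx)
            holdout = dev.take_samples(rest_idx)
            cfg = dataclasses.replace(config, rng_seed=int(seeds[1]))
            mc = train_master(subset, cfg)
            res = evaluate_development(
                mc, subset, holdout if holdout.n_samples else None
            )
            val_auc = roc_auc(
                mc.score(val, mode="full"), val.labels
            ).auc
            rows.append((size, rep, "dev_oob", res["oob"].auc))
            if res["int_val"] is not None:
                rows.append((size, rep, "dev_int_val", res["int_val"].auc))
            rows.append((size, rep, "dev_all", res["all"].auc))
            rows.append((size, rep, "val", val_auc))
    return pd.DataFrame(
        rows, columns=["size_per_class", "realization", "mode", "auc"]
    )


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE of AUC per (size_per_class, mode)."""

    def _se(x: pd.Series) -> float:
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan

    out = (
        df.groupby(["size_per_class", "mode"])["auc"]
        .agg(mean="mean", se=_se, n="count")
        .reset_index()
    )
    return out
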