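"""Synthetic expression-data generators for end-to-end testing.

Three study designs are emulated with two-class Gaussian data:

* a plain two-class problem: a handful of informative features whose
  class means differ by a standardized effect size, plus pure-noise
  features (mean 0, SD 1), with an independent validation cohort drawn
  from the same population;
* the "very many useless features" design: any dataset can be augmented
  with blocks of i.i.d. N(0,1) noise features;
* a confounded design: a hidden binary confounder (think tumor histology)
  shifts its own feature block and is associated with the class label in
  the development cohort but not in validation, plus a small external set
  of unlabeled samples drawn from a single confounder stratum — the raw
  material for external-set filtering.

The generators deliberately use independent Gaussian features rather than
a realistic transcriptome covariance: what the pipeline must cope with is
the *dimensionality* and, in the confounded design, a second
easier-to-learn signal, not microarray noise structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import ExpressionDataset

__all__ = [
    "ConfounderSpec",
    "FixtureSpec",
    "make_two_class_gaussian",
    "add_noise_features",
    "make_confounded_pair",
]


@dataclass
class ConfounderSpec:
    """Hidden binary confounder linked to class in development only.

    ``dev_association`` a in [0, 1] sets P(c=1 | y=1) = 0.5 + a/2 and
    P(c=1 | y=0) = 0.5 - a/2 in the development cohort (a=1: perfect
    confounding; a=0: independence). In validation the association is
    ``val_association`` (0 for a realistic unconfounded population).
    ``n_confounded`` features shift with the confounder by
    ``confounder_effect``; ``n_mixed`` features carry both signals at half
    strength each (real transcriptomes have genes associated with both the
    endpoint and the confounder, and these partially-confounded features
    are what a progressively tightened external filter keeps pruning).
    The external set holds ``n_ambiguous_external`` unlabeled samples
    drawn from the c=0 stratum only, with a balanced true-class mix
    (alive-leaning for odd sizes).
    """

    dev_association: float = 0.7
    val_association: float = 0.0
    confounder_effect: float = 1.6
    n_confounded: int = 30
    n_mixed: int = 30
    n_ambiguous_external: int = 9

    def __post_init__(self) -> None:
        for name in ("dev_association", "val_association"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_confounded < 1 or self.n_ambiguous_external < 1:
            raise ValueError("n_confounded and n_ambiguous_external must be >= 1")
        if self.n_mixed < 0:
            raise ValueError("n_mixed must be non-negative")


@dataclass
class FixtureSpec:
    """Shape and signal strength of a synthetic two-class dataset pair."""

    n_per_class_dev: int = 40
    n_per_class_val: int = 200
    n_informative: int = 0
    n_noise: int = 200
    effect_size: float = 1.0
    confounder: Optional[ConfounderSpec] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.n_per_class_dev < 1 or self.n_per_class_val < 1:
            raise ValueError("per-class sample counts must be positive")


def _feature_ids(spec: FixtureSpec) -> list[str]:
    ids = [f"inf_{j + 1:04d}" for j in range(spec.n_informative)]
    ids += [f"noise_{j + 1:05d}" for j in range(spec.n_noise)]
    return ids


def _draw_cohort(
    spec: FixtureSpec, n_per_class: int, prefix: str, rng: np.random.Generator
) -> ExpressionDataset:
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    X = rng.standard_normal((n, spec.n_informative + spec.n_noise))
    if spec.n_informative:
        X[:, : spec.n_informative] += (
            (y - 0.5)[:, None] * spec.effect_size
        )
    perm = rng.permutation(n)
    return ExpressionDataset(
        sample_ids=[f"{prefix}_s{i + 1:04d}" for i in range(n)],
        feature_ids=_feature_ids(spec),
        values=X[perm],
        labels=y[perm],
    )


def make_two_class_gaussian(
    spec: FixtureSpec,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Development and validation cohorts drawn i.i.d. from one population.

    Informative features are N(+-effect_size/2, 1) by class (standardized
    mean difference = effect_size, so a single informative feature has
    population AUC Phi(effect_size / sqrt(2))); noise features are N(0,1).
    Reproducible given ``spec.rng_seed``.
    """
    ss = np.random.SeedSequence(spec.rng_seed)
    dev_ss, val_ss = ss.spawn(2)
    dev = _draw_cohort(
        spec, spec.n_per_class_dev, "dev", np.random.default_rng(dev_ss)
    )
    val = _draw_cohort(
        spec, spec.n_per_class_val, "val", np.random.default_rng(val_ss)
    )
    return dev, val


def add_noise_features(
    ds: ExpressionDataset, n_noise: int, rng_seed: int = 0
) -> ExpressionDataset:
    """Append ``n_noise`` i.i.d. N(0,1) features with reserved IDs.

    Emulates augmenting a real expression matrix with thousands of
    randomly generated features; call with distinct seeds for development
    and validation so the noise is independent across cohorts.
    """
    if n_noise == 0:
        return ds
    if n_noise < 0:
        raise ValueError("n_noise must be non-negative")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal((ds.n_samples, n_noise))
    existing = set(ds.feature_ids)
    ids, j = [], 0
    while len(ids) < n_noise:
        j += 1
        fid = f"noise_{j:05d}"
        if fid not in existing:
            ids.append(fid)
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        feature_ids=list(ds.feature_ids) + ids,
        values=np.concatenate([ds.values, noise], axis=1),
        labels=ds.labels,
        survival_time=ds.survival_time,
        survival_event=ds.survival_event,
    )


def _confounded_cohort(
    spec: FixtureSpec,
    n_per_class: int,
    association: float,
    prefix: str,
    rng: np.random.Generator,
) -> tuple[ExpressionDataset, np.ndarray]:
    conf = spec.confounder
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    p_c1 = np.where(y == 1, 0.5 + association / 2.0, 0.5 - association / 2.0)
    c = (rng.random(n) < p_c1).astype(int)
    X = _confounded_matrix(spec, y, c, rng)
    perm = rng.permutation(n)
    ds = ExpressionDataset(
        sample_ids=[f"{prefix}_s{i + 1:04d}" for i in range(n)],
        feature_ids=_confounded_feature_ids(spec),
        values=X[perm],
        labels=y[perm],
    )
    return ds, c[perm]


def _confounded_feature_ids(spec: FixtureSpec) -> list[str]:
    conf = spec.confounder
    ids = [f"cls_{j + 1:04d}" for j in range(spec.n_informative)]
    ids += [f"conf_{j + 1:04d}" for j in range(conf.n_confounded)]
    ids += [f"mixed_{j + 1:04d}" for j in range(conf.n_mixed)]
    ids += [f"noise_{j + 1:05d}" for j in range(spec.n_noise)]
    return ids


def _confounded_matrix(
    spec: FixtureSpec,
    y: np.ndarray,
    c: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    conf = spec.confounder
    p = spec.n_informative + conf.n_confounded + conf.n_mixed + spec.n_noise
    X = rng.standard_normal((y.size, p))
    if spec.n_informative:
        X[:, : spec.n_informative] += (y - 0.5)[:, None] * spec.effect_size
    lo = spec.n_informative
    hi = lo + conf.n_confounded
    X[:, lo:hi] += (c - 0.5)[:, None] * conf.confounder_effect
    lo, hi = hi, hi + conf.n_mixed
    X[:, lo:hi] += (
        (y - 0.5)[:, None] * (spec.effect_size / 2.0)
        + (c - 0.5)[:, None] * (conf.confounder_effect / 2.0)
    )
    return X


def make_confounded_pair(
    spec: FixtureSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Confounded development cohort, clean validation cohort, external set.

    One feature block shifts with the true class (strength
    ``effect_size``), a second with a hidden binary confounder (strength
    ``confounder_effect``). The confounder is associated with the class in
    development (``dev_association``) but not in validation, emulating a
    convenience development cohort whose class balance is skewed by, e.g.,
    tumor histology. The external set contains unlabeled samples from the
    c=0 stratum only with a balanced true-class mix — samples unusable for
    training that an external filtering constraint can exploit.
    """
    if spec.confounder is None:
        raise ValueError("FixtureSpec.confounder must be set")
    conf = spec.confounder
    ss = np.random.SeedSequence(spec.rng_seed)
    dev_ss, val_ss, ext_ss = ss.spawn(3)
    dev, _ = _confounded_cohort(
        spec, spec.n_per_class_dev, conf.dev_association, "dev",
        np.random.default_rng(dev_ss),
    )
    val, _ = _confounded_cohort(
        spec, spec.n_per_class_val, conf.val_association, "val",
        np.random.default_rng(val_ss),
    )
    rng = np.random.default_rng(ext_ss)
    n_ext = conf.n_ambiguous_external
    y_ext = np.tile([1, 0], (n_ext + 1) // 2)[:n_ext]
    c_ext = np.zeros(n_ext, dtype=int)
    X_ext = _confounded_matrix(spec, y_ext, c_ext, rng)
    external = ExpressionDataset(
        sample_ids=[f"ext_s{i + 1:04d}" for i in range(n_ext)],
        feature_ids=_confounded_feature_ids(spec),
        values=X_ext,
        labels=None,
    )
    return dev, val, external
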