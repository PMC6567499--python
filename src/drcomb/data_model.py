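"""Expression dataset container and in-scope preprocessing.

The central object is :class:`ExpressionDataset`: a samples x features
real-valued matrix with sample/feature identifiers, optional binary class
labels (convention: 1 = the clinically "positive" class, e.g. alive at the
survival horizon) and optional survival annotations (time, event).

Preprocessing covers only what classifier development needs once expression
matrices are already normalized and batch-adjusted upstream: averaging of
duplicate feature (probe) columns, restriction of two cohorts to their
common feature set, and dichotomization of survival data at a fixed horizon
with removal of samples whose follow-up is too short to assign a class.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SurvivalDichotomy",
    "load_expression_dataset",
    "write_expression_dataset",
    "average_duplicate_features",
    "intersect_features",
    "dichotomize_survival",
]


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with per-sample annotations.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    feature_ids : list of str
        Feature identifiers, one per matrix column. Duplicates are allowed
        (multiple probes per gene) until :func:`average_duplicate_features`
        is applied.
    values : ndarray of shape (n_samples, n_features)
        Real-valued expression matrix; no missing values.
    labels : ndarray of shape (n_samples,), optional
        Binary class labels in {0, 1}; 1 is the positive class.
    survival_time, survival_event : ndarray of shape (n_samples,), optional
        Follow-up time (non-negative, single consistent unit) and event
        indicator (1 = death observed, 0 = censored).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None
    survival_time: Optional[np.ndarray] = None
    survival_event: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x features)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids but {n} matrix rows"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids but {p} matrix columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal number of samples")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")
        for arr_name in ("survival_time", "survival_event"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{arr_name} length must equal samples")
                setattr(self, arr_name, arr)
        if self.survival_time is not None and (self.survival_time < 0).any():
            raise ValueError("negative survival time")
        if self.survival_event is not None and not np.isin(
            self.survival_event, (0.0, 1.0)
        ).all():
            raise ValueError("survival event must be 0 or 1")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def take_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Return a new dataset restricted to the given sample rows."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
            survival_time=None
            if self.survival_time is None
            else self.survival_time[idx],
            survival_event=None
            if self.survival_event is None
            else self.survival_event[idx],
        )

    def take_features(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Return a new dataset restricted to the given feature columns."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels,
            survival_time=self.survival_time,
            survival_event=self.survival_event,
        )


@dataclass
class SurvivalDichotomy:
    """Result of dichotomizing survival at a horizon.

    ``included`` carries binary labels (1 = alive at the horizon); samples
    censored before the horizon cannot be assigned a class and are set
    aside in ``ambiguous`` (unlabeled). Together they partition the input.
    """

    horizon: float
    included: ExpressionDataset
    ambiguous: ExpressionDataset


def _read_delimited(path: str | os.PathLike, sep: Optional[str]) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, header=0, float_precision="round_trip"
    )
    return df


def load_expression_dataset(
    matrix_path: str | os.PathLike,
    annotation_path: Optional[str | os.PathLike] = None,
    orientation: str = "samples_as_rows",
    sep: Optional[str] = None,
) -> ExpressionDataset:
    """Load an expression matrix (and optional annotations) from delimited text.

    The matrix file has a header row and an identifier first column. With
    ``orientation="samples_as_rows"`` rows are samples; with
    ``"features_as_rows"`` the file is transposed after reading. The
    annotation file is keyed by ``sample_id`` and may carry ``label``
    and/or ``time``/``event`` columns. Samples present in only one of the
    two files are dropped (with a warning via ``warnings``).

    Missing or non-numeric matrix cells are hard errors: imputation is out
    of scope and silent coercion would corrupt downstream distances.
    """
    import warnings

    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(matrix_path, sep)
    if orientation == "features_as_rows":
        df = df.T
    # locate non-numeric / missing cells precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raw = df.iat[i, j]
        kind = "missing value" if pd.isna(raw) or str(raw).upper() in ("NA", "NAN", "") else "non-numeric cell"
        raise ValueError(
            f"{kind} {raw!r} at sample {df.index[i]!r}, feature {df.columns[j]!r} "
            f"in {matrix_path}"
        )
    sample_ids = [str(s) for s in numeric.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ID in {matrix_path}")
    feature_ids = [str(f) for f in numeric.columns]
    values = numeric.to_numpy(dtype=float)

    labels = time = event = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, float_precision="round_trip")
        if "sample_id" not in ann.columns:
            raise ValueError("annotation file must have a 'sample_id' column")
        ann["sample_id"] = ann["sample_id"].astype(str)
        if ann["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ID in annotation file")
        ann = ann.set_index("sample_id")
        common = [s for s in sample_ids if s in ann.index]
        dropped = (len(sample_ids) - len(common)) + (len(ann) - len(common))
        if dropped:
            warnings.warn(
                f"{dropped} samples present in only one file were dropped"
            )
        keep = [i for i, s in enumerate(sample_ids) if s in ann.index]
        values = values[keep]
        sample_ids = [sample_ids[i] for i in keep]
        ann = ann.loc[sample_ids]
        if "label" in ann.columns:
            labels = ann["label"].to_numpy()
        if "time" in ann.columns:
            time = ann["time"].to_numpy(dtype=float)
        if "event" in ann.columns:
            event = ann["event"].to_numpy(dtype=float)
    return ExpressionDataset(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        values=values,
        labels=labels,
        survival_time=time,
        survival_event=event,
    )


def write_expression_dataset(
    ds: ExpressionDataset,
    matrix_path: str | os.PathLike,
    annotation_path: Optional[str | os.PathLike] = None,
    sep: Optional[str] = None,
) -> None:
    """Write the matrix (and annotations if any) as delimited text.

    Inverse of :func:`load_expression_dataset`; a write/load round trip
    reproduces the dataset exactly up to float formatting (full ``repr``
    precision is used so values survive the round trip bit-exactly).
    """
    if sep is None:
        sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep=sep, float_format="%.17g")
    if annotation_path is not None:
        cols: dict[str, np.ndarray] = {}
        if ds.labels is not None:
            cols["label"] = ds.labels
        if ds.survival_time is not None:
            cols["time"] = ds.survival_time
        if ds.survival_event is not None:
            cols["event"] = ds.survival_event
        ann = pd.DataFrame(cols, index=pd.Index(ds.sample_ids, name="sample_id"))
        ann.to_csv(annotation_path, float_format="%.17g")


def average_duplicate_features(ds: ExpressionDataset) -> ExpressionDataset:
    """Average columns that share a feature ID (multiple probes per gene).

    Resulting feature IDs are unique, ordered by first occurrence.
    Idempotent: a dataset with unique feature IDs is returned unchanged
    (same arrays, new container).
    """
    order: dict[str, list[int]] = {}
    for j, f in enumerate(ds.feature_ids):
        order.setdefault(f, []).append(j)
    if all(len(v) == 1 for v in order.values()):
        return ExpressionDataset(
            sample_ids=list(ds.sample_ids),
            feature_ids=list(ds.feature_ids),
            values=ds.values.copy(),
            labels=ds.labels,
            survival_time=ds.survival_time,
            survival_event=ds.survival_event,
        )
    feature_ids = list(order.keys())
    values = np.column_stack(
        [ds.values[:, cols].mean(axis=1) for cols in order.values()]
    )
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        feature_ids=feature_ids,
        values=values,
        labels=ds.labels,
        survival_time=ds.survival_time,
        survival_event=ds.survival_event,
    )


def intersect_features(
    a: ExpressionDataset, b: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict two cohorts to their common features, in lexicographic order.

    Used to make a development and a validation cohort comparable when they
    were profiled on different platforms. Both datasets must already have
    unique feature IDs; an empty intersection is an error.
    """
    for ds, name in ((a, "first"), (b, "second")):
        if len(set(ds.feature_ids)) != len(ds.feature_ids):
            raise ValueError(
                f"{name} dataset has duplicate feature IDs; "
                "apply average_duplicate_features first"
            )
    common = sorted(set(a.feature_ids) & set(b.feature_ids))
    if not common:
        raise ValueError("feature sets are disjoint: empty intersection")
    a_pos = {f: j for j, f in enumerate(a.feature_ids)}
    b_pos = {f: j for j, f in enumerate(b.feature_ids)}
    return (
        a.take_features([a_pos[f] for f in common]),
        b.take_features([b_pos[f] for f in common]),
    )


def dichotomize_survival(
    ds: ExpressionDataset, horizon: float
) -> SurvivalDichotomy:
    """Dichotomize survival at ``horizon``: alive (1) vs dead (0).

    A sample is labeled 1 when its follow-up time reaches the horizon
    (time >= horizon, regardless of the event flag: surviving exactly to
    the horizon counts as alive), 0 when death was observed before the
    horizon. Samples censored before the horizon cannot be classified and
    are returned unlabeled in ``ambiguous``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if ds.survival_time is None or ds.survival_event is None:
        raise ValueError("dataset has no survival annotations")
    time, event = ds.survival_time, ds.survival_event
    alive = time >= horizon
    dead = (event == 1) & (time < horizon)
    ambiguous = (event == 0) & (time < horizon)
    inc_idx = np.flatnonzero(alive | dead)
    amb_idx = np.flatnonzero(ambiguous)
    included = ds.take_samples(inc_idx)
    included.labels = alive[inc_idx].astype(int)
    amb = ds.take_samples(amb_idx)
    amb.labels = None
    return SurvivalDichotomy(horizon=horizon, included=included, ambiguous=amb)
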