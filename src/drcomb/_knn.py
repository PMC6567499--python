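"""Vectorized k-nearest-neighbor vote engine.

All atomic-classifier and baseline kNN paths funnel through
:func:`votes_from_dists`, which counts class-1 labels among the k nearest
reference points for every query, with a deterministic tie rule: among
reference points exactly equidistant at the neighborhood boundary, the one
with the lower reference-row index is admitted first. The implementation is
O(n) per query (argpartition + counting) rather than a full sort, but is
exactly equivalent to a stable sort by (distance, index).

Distances for feature subsets are assembled from per-feature squared
Euclidean distance blocks, so pairs/triplets cost one or two extra adds per
entry instead of a fresh distance computation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

try:  # numba accelerates the many-subset sweeps; numpy path is equivalent
    import numba as _nb
except ImportError:  # pragma: no cover
    _nb = None

# Soft cap on scratch elements per chunk when sweeping many subsets.
_CHUNK_ELEMENTS = 8_000_000


def votes_from_dists(
    dists: np.ndarray,
    labels_mask: np.ndarray,
    k: int,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Count class-1 labels among the k nearest references per query.

    Parameters
    ----------
    dists : ndarray, shape (..., m, n)
        Squared (or any monotone) distances from m queries to n references.
        Modified in place when ``exclude`` is given.
    labels_mask : bool ndarray, shape (n,)
        True where the reference point belongs to class 1.
    k : int
        Neighborhood size, 1 <= k <= number of usable references.
    exclude : int ndarray, shape (m,), optional
        Per-query reference index to exclude (-1 for none); used for
        self-exclusion when queries are the reference set itself.

    Returns
    -------
    votes : int ndarray, shape (..., m)
    """
    d = np.asarray(dists)
    n = d.shape[-1]
    m = d.shape[-2]
    if exclude is not None:
        q_idx = np.arange(m)
        sel = exclude >= 0
        d[..., q_idx[sel], exclude[sel]] = np.inf
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == n:
        # all references are neighbors (exclusions contribute inf but are
        # still counted structurally only when k < usable count; guard)
        usable = np.isfinite(d).sum(axis=-1)
        if (usable < k).any():
            raise ValueError("k exceeds usable reference count after exclusion")
    part = np.argpartition(d, k - 1, axis=-1)[..., :k]
    kth = np.take_along_axis(d, part, axis=-1).max(axis=-1, keepdims=True)
    less = d < kth
    n_less = less.sum(axis=-1, dtype=np.int32)
    votes = (less & labels_mask).sum(axis=-1, dtype=np.int32)
    need = (k - n_less).astype(np.int32)
    eq = d == kth[..., :]
    # admit ties in reference-index order until the neighborhood is full
    cum = np.cumsum(eq, axis=-1, dtype=np.int32)
    chosen = eq & (cum <= need[..., None])
    votes += (chosen & labels_mask).sum(axis=-1, dtype=np.int32)
    return votes


def sq_dists(queries: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Full squared Euclidean distance matrix, shape (m, n)."""
    diff = queries[:, None, :] - refs[None, :, :]
    return np.einsum("mnp,mnp->mn", diff, diff)


if _nb is not None:

    @_nb.njit(cache=True, fastmath=False)
    def _subset_votes_kernel(ref_t, queries, subsets, labels, k, exclude, out):
        S, w = subsets.shape
        m = queries.shape[0]
        n = ref_t.shape[1]
        dbuf = np.empty(n)
        kd = np.empty(k)
        qv = np.empty(w)
        for s in range(S):
            order = 0
            for t in range(w):
                if subsets[s, t] < 0:
                    break
                order += 1
            for j in range(m):
                for t in range(order):
                    qv[t] = queries[j, subsets[s, t]]
                # distances feature-by-feature over contiguous reference rows
                f0 = subsets[s, 0]
                q0 = qv[0]
                for i in range(n):
                    diff = q0 - ref_t[f0, i]
                    dbuf[i] = diff * diff
                for t in range(1, order):
                    ft = subsets[s, t]
                    qt = qv[t]
                    for i in range(n):
                        diff = qt - ref_t[ft, i]
                        dbuf[i] += diff * diff
                if exclude[j] >= 0:
                    dbuf[exclude[j]] = np.inf
                cnt = 0
                for i in range(n):
                    d = dbuf[i]
                    # maintain the k smallest distance values (ascending)
                    if cnt < k:
                        pos = cnt
                        while pos > 0 and kd[pos - 1] > d:
                            kd[pos] = kd[pos - 1]
                            pos -= 1
                        kd[pos] = d
                        cnt += 1
                    elif d < kd[k - 1]:
                        pos = k - 1
                        while pos > 0 and kd[pos - 1] > d:
                            kd[pos] = kd[pos - 1]
                            pos -= 1
                        kd[pos] = d
                kth = kd[k - 1]
                votes = 0
                need = k
                for i in range(n):
                    if dbuf[i] < kth:
                        need -= 1
                        if labels[i]:
                            votes += 1
                # ties at the boundary: admit in reference-index order
                for i in range(n):
                    if need == 0:
                        break
                    if dbuf[i] == kth:
                        need -= 1
                        if labels[i]:
                            votes += 1
                out[s, j] = votes


def _subset_votes_numba(
    ref: np.ndarray,
    queries: np.ndarray,
    subsets_padded: np.ndarray,
    labels_mask: np.ndarray,
    k: int,
    exclude: Optional[np.ndarray],
) -> np.ndarray:
    n, p = ref.shape
    m = queries.shape[0]
    S = subsets_padded.shape[0]
    subs = np.where(subsets_padded >= p, -1, subsets_padded).astype(np.int64)
    excl = (
        np.full(m, -1, dtype=np.int64)
        if exclude is None
        else np.asarray(exclude, dtype=np.int64)
    )
    out = np.empty((S, m), dtype=np.int32)
    _subset_votes_kernel(
        np.ascontiguousarray(np.asarray(ref, dtype=np.float64).T),
        np.ascontiguousarray(queries, dtype=np.float64),
        np.ascontiguousarray(subs),
        labels_mask.astype(np.uint8),
        k,
        excl,
        out,
    )
    return out


def subset_votes(
    ref: np.ndarray,
    queries: np.ndarray,
    subsets_padded: np.ndarray,
    labels_mask: np.ndarray,
    k: int,
    exclude: Optional[np.ndarray] = None,
    dtype: np.dtype = np.float64,
) -> np.ndarray:
    """kNN class-1 vote counts for many feature subsets at once.

    ``subsets_padded`` is an (S, w) int array of column indices into
    ``ref``/``queries`` (already transformed coordinates), padded with the
    sentinel value ``ref.shape[1]`` which contributes zero distance.

    Returns an (S, m) int array of votes.
    """
    if exclude is not None and k >= ref.shape[0]:
        raise ValueError("k exceeds usable reference count after exclusion")
    if _nb is not None:
        return _subset_votes_numba(
            ref, queries, subsets_padded, labels_mask, k, exclude
        )
    n, p = ref.shape
    m = queries.shape[0]
    S, w = subsets_padded.shape
    votes = np.empty((S, m), dtype=np.int32)
    # per-feature squared distance blocks, plus a zero block for padding
    q_chunk = max(1, min(m, _CHUNK_ELEMENTS // max(1, (p + 1) * n)))
    for q0 in range(0, m, q_chunk):
        q1 = min(m, q0 + q_chunk)
        qs = queries[q0:q1]
        mq = q1 - q0
        dfeat = np.empty((p + 1, mq, n), dtype=dtype)
        diff = qs.T[:, :, None] - ref.T[:, None, :]
        np.multiply(diff, diff, out=dfeat[:p])
        dfeat[p] = 0.0
        excl = None if exclude is None else exclude[q0:q1]
        s_chunk = max(1, _CHUNK_ELEMENTS // max(1, mq * n))
        for s0 in range(0, S, s_chunk):
            s1 = min(S, s0 + s_chunk)
            sub = subsets_padded[s0:s1]
            d = dfeat[sub[:, 0]].copy()
            for col in range(1, w):
                d += dfeat[sub[:, col]]
            if excl is not None:
                # re-apply per subset-chunk; votes_from_dists mutates d only
                pass
            votes[s0:s1, q0:q1] = votes_from_dists(
                d, labels_mask, k,
                None if excl is None else np.broadcast_to(excl, (mq,)).copy(),
            )
    return votes


def rank_fit(train_col: np.ndarray) -> np.ndarray:
    """Sorted training values: the fitted state of the rank transform."""
    return np.sort(np.asarray(train_col, dtype=float))


def rank_apply(sorted_train: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Map values onto the training rank scale.

    A value equal to training value(s) receives their average-tie rank
    (#below + (#ties + 1)/2); a value strictly between / outside training
    values receives #below + 1, so queries interleave with integer ranks
    and every training point maps to its own rank.
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    lo = np.searchsorted(sorted_train, v, side="left")
    hi = np.searchsorted(sorted_train, v, side="right")
    eq = hi - lo
    out = np.where(eq > 0, lo + (eq + 1) / 2.0, lo + 1.0)
    if np.isscalar(values) or np.asarray(values).ndim == 0:
        return out[0]
    return out
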