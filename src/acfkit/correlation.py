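"""Pairwise correlations under pairwise deletion.

Every statistic here is computed only over the features observed in *both*
samples of a pair (pairwise deletion), never by imputing.  An entry is
*undefined* — returned as NaN, never as an exception and never as a silent
zero — when the overlap has fewer than ``min_overlap`` points or either
subvector is constant on the overlap.

Pearson matrices are assembled with masked matrix products, which makes the
all-pairs computation O(n_rows * n_cols * n_features) in BLAS rather than a
Python loop.  Pearson is invariant to shifting/scaling each sample, so rows
are standardised on their observed values first; this also keeps the running
sums well conditioned for data far from zero.  Spearman requires re-ranking
each overlap subvector, so it falls back to a per-pair loop.

The module keeps an operation counter (:func:`count_pairs`) so that
complexity contracts — e.g. that a fast-ACF prediction touches exactly
``sum_C n_ref(C)`` training samples regardless of the training-set size —
can be asserted rather than argued.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy import stats

from .containers import CorrelationMatrix, OmicsMatrix

__all__ = [
    "pairwise_correlation",
    "train_correlation_matrix",
    "cross_correlation_matrix",
    "count_pairs",
]

DEFAULT_MIN_OVERLAP = 3

# variance below this (after per-row standardisation) counts as constant
_VAR_TOL = 1e-10


class _PairCounter:
    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0


_ACTIVE_COUNTERS: list[_PairCounter] = []


@contextmanager
def count_pairs():
    """Context manager yielding a counter of pairwise computations.

    ``counter.count`` is incremented by one for every (row, col) pair whose
    correlation is computed while the context is active.
    """
    counter = _PairCounter()
    _ACTIVE_COUNTERS.append(counter)
    try:
        yield counter
    finally:
        _ACTIVE_COUNTERS.remove(counter)


def _record_pairs(n: int) -> None:
    for counter in _ACTIVE_COUNTERS:
        counter.count += n


def pairwise_correlation(x, y, method: str = "pearson",
                         min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Correlation of two feature vectors over their joint observed support.

    Returns NaN (undefined) when fewer than ``min_overlap`` features are
    observed in both vectors or either subvector is constant on the overlap.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    _record_pairs(1)
    ov = np.isfinite(x) & np.isfinite(y)
    if ov.sum() < max(int(min_overlap), 2):
        return float("nan")
    xs, ys = x[ov], y[ov]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    if method == "spearman":
        xs = stats.rankdata(xs)  # average ranks for ties
        ys = stats.rankdata(ys)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return float("nan")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _standardise_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre/scale each row on its observed entries; return (z, mask)."""
    mask = np.isfinite(values)
    z = np.where(mask, values, 0.0)
    n_obs = mask.sum(axis=1, keepdims=True).astype(float)
    n_obs[n_obs == 0] = 1.0
    mean = z.sum(axis=1, keepdims=True) / n_obs
    z = np.where(mask, z - mean, 0.0)
    sd = np.sqrt((z ** 2).sum(axis=1, keepdims=True) / n_obs)
    sd[sd == 0] = 1.0
    return z / sd, mask


def _masked_pearson(A: np.ndarray, B: np.ndarray, min_overlap: int) -> np.ndarray:
    """All-pairs Pearson between rows of A and rows of B with NaN masking."""
    za, ma = _standardise_rows(A)
    zb, mb = _standardise_rows(B)
    maf = ma.astype(float)
    mbf = mb.astype(float)
    n_ov = maf @ mbf.T
    sx = za @ mbf.T
    sy = maf @ zb.T
    sxx = (za ** 2) @ mbf.T
    syy = maf @ (zb ** 2).T
    sxy = za @ zb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n_ov
        varx = sxx - sx ** 2 / n_ov
        vary = syy - sy ** 2 / n_ov
        r = cov / np.sqrt(varx * vary)
    bad = (n_ov < max(int(min_overlap), 2)) | (varx <= _VAR_TOL * n_ov) | \
          (vary <= _VAR_TOL * n_ov)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r


def _pairwise_spearman(A: np.ndarray, B: np.ndarray, min_overlap: int,
                       symmetric: bool) -> np.ndarray:
    out = np.full((A.shape[0], B.shape[0]), np.nan)
    for i in range(A.shape[0]):
        j0 = i if symmetric else 0
        for j in range(j0, B.shape[0]):
            ov = np.isfinite(A[i]) & np.isfinite(B[j])
            if ov.sum() < max(int(min_overlap), 2):
                continue
            xs = stats.rankdata(A[i, ov])
            ys = stats.rankdata(B[j, ov])
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            out[i, j] = np.clip(r, -1.0, 1.0)
            if symmetric:
                out[j, i] = out[i, j]
    return out


def _build(A: np.ndarray, B: np.ndarray, method: str, min_overlap: int,
           symmetric: bool) -> np.ndarray:
    _record_pairs(A.shape[0] * B.shape[0])
    if method == "pearson":
        r = _masked_pearson(A, B, min_overlap)
        if symmetric:
            # exact symmetry: float matmuls are not order-invariant
            iu = np.triu_indices_from(r, k=1)
            r[(iu[1], iu[0])] = r[iu]
        return r
    return _pairwise_spearman(A, B, min_overlap, symmetric)


def train_correlation_matrix(X: OmicsMatrix, method: str = "pearson",
                             min_overlap: int = DEFAULT_MIN_OVERLAP) -> CorrelationMatrix:
    """Square symmetric matrix of all train-vs-train pairwise correlations.

    Diagonal entries are 1 where the sample has at least ``min_overlap``
    observed, non-constant features (undefined otherwise).
    """
    r = _build(X.values, X.values, method, min_overlap, symmetric=True)
    return CorrelationMatrix(r, list(X.sample_ids), list(X.sample_ids),
                             method=method, min_overlap=min_overlap)


def cross_correlation_matrix(X_test: OmicsMatrix, X_train: OmicsMatrix,
                             method: str = "pearson",
                             min_overlap: int = DEFAULT_MIN_OVERLAP) -> CorrelationMatrix:
    """Rectangular test x train correlation matrix.

    Both matrices must share an identical feature space (ids and order).
    """
    if list(X_test.feature_ids) != list(X_train.feature_ids):
        raise ValueError("test and train matrices have different feature spaces")
    r = _build(X_test.values, X_train.values, method, min_overlap, symmetric=False)
    return CorrelationMatrix(r, list(X_test.sample_ids), list(X_train.sample_ids),
                             method=method, min_overlap=min_overlap)
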