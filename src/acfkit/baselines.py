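"""Correlation-based comparator classifiers: brute KNN and DBC.

Both work directly on pairwise-deletion correlation matrices and serve as
the reference points the ACF estimator is measured against.

* **KNN** ranks training samples by correlation (highest = nearest; brute
  search, no tree acceleration) and takes a majority vote among the top K.
  Optional random oversampling balances the training classes first, which
  lets hyperparameter search pick larger K on imbalanced data.
* **DBC** (distribution-based classification) approximates, for every
  ordered class pair, the empirical distribution of pairwise correlations
  with a fixed-bin histogram and decides in two stages.  First the claiming
  stage: every class i inspects the test sample's histogram of correlations
  to i's own members and claims the sample if that histogram is closer (in
  Kullback–Leibler distance) to the intra-class distribution D_ii than to
  any of i's inter-class distributions D_ij.  Then the weighted KL rule:
  among the claimants (or among all classes when no class claims), the
  sample is assigned to the class i whose full distribution profile
  {D_ij}_j minimises the equally-weighted sum of KL distances to the
  sample's per-class histograms — every class pair contributes equally,
  regardless of class abundance.  DBC is parameter-free at the user level.
  **F-DBC** approximates the class distributions from a fixed number of
  reference instances per class.

  Histograms are smoothed by mixing with the uniform distribution at a
  small fixed weight, which keeps every KL distance finite without tying
  the amount of smoothing to the class size (count-based pseudo-counts
  systematically flatten small-class histograms, which biases the KL rule
  toward minority classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import correlation
from .acf import select_references, _class_order
from .containers import CorrelationMatrix, OmicsMatrix

__all__ = [
    "knn_predict",
    "random_oversample",
    "estimate_class_distributions",
    "kl_distance",
    "dbc_predict",
    "CorrelationKNN",
    "DBCClassifier",
]

DBC_BINS = 20
DBC_SMOOTHING = 0.01  # uniform-mixture weight of the histogram smoothing
_EPS_DIST = 1e-6  # floor for the 1 - r vote-weight denominator


def knn_predict(C_cross: CorrelationMatrix | np.ndarray, labels: Sequence,
                k: int, weights: str = "uniform") -> np.ndarray:
    """Majority vote among the K most-correlated training samples.

    Undefined correlations rank last (they are the least trustworthy
    neighbours), never raise.  ``weights='distance'`` converts correlation r
    to distance d = 1 - r and weights each vote by 1/max(d, eps).  Ties
    between classes are broken toward the class with the larger summed
    correlation among its voting neighbours, then by label order.
    """
    entries = C_cross.entries if isinstance(C_cross, CorrelationMatrix) else np.asarray(C_cross, float)
    labels = np.asarray(labels, dtype=object)
    if labels.size != entries.shape[1]:
        raise ValueError("one label per training column required")
    n_train = entries.shape[1]
    if not 1 <= k <= n_train:
        raise ValueError(f"K must be in [1, {n_train}], got {k}")
    if weights not in ("uniform", "distance"):
        raise ValueError(f"unknown weighting {weights!r}")

    classes = np.asarray(_class_order(labels), dtype=object)
    codes = np.searchsorted(classes, labels)
    ranked = np.where(np.isfinite(entries), entries, -np.inf)
    top = np.argsort(-ranked, axis=1, kind="stable")[:, :k]
    r = np.take_along_axis(ranked, top, axis=1)
    if weights == "uniform":
        w = np.ones_like(r)
    else:
        w = 1.0 / np.maximum(1.0 - r, _EPS_DIST)
        w[~np.isfinite(w)] = 0.0  # undefined neighbours cast no vote
    neigh_codes = codes[top]
    r_fin = np.where(np.isfinite(r), r, 0.0)
    votes = np.stack([(w * (neigh_codes == c)).sum(axis=1)
                      for c in range(classes.size)], axis=1)
    corr_sum = np.stack([(r_fin * (neigh_codes == c)).sum(axis=1)
                         for c in range(classes.size)], axis=1)
    # tie-break: summed correlation among tied classes, then label order
    is_top = votes == votes.max(axis=1, keepdims=True)
    tie_sum = np.where(is_top, corr_sum, -np.inf)
    winner = np.argmax(tie_sum == tie_sum.max(axis=1, keepdims=True), axis=1)
    return classes[winner]


def random_oversample(labels: Sequence, seed: int | None = None) -> np.ndarray:
    """Indices bringing every class up to the majority-class count.

    All original indices are kept in order; minority classes are topped up
    by sampling their own indices with replacement.  On balanced labels the
    result is the identity.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label vector")
    rng = np.random.default_rng(seed)
    counts = {c: int((labels == c).sum()) for c in _class_order(labels)}
    target = max(counts.values())
    out = [np.arange(labels.size)]
    for cls in _class_order(labels):
        idx = np.flatnonzero(labels == cls)
        deficit = target - idx.size
        if deficit > 0:
            out.append(rng.choice(idx, size=deficit, replace=True))
    return np.concatenate(out)


def _histogram(values: np.ndarray, bins: int,
               smoothing: float = DBC_SMOOTHING) -> np.ndarray:
    """Normalised histogram on [-1, 1], mixed with the uniform distribution.

    The fixed-weight uniform mixture keeps every Kullback–Leibler distance
    finite while smoothing all histograms by the same amount irrespective
    of how many observations back them.
    """
    counts, _ = np.histogram(values, bins=bins, range=(-1.0, 1.0))
    p = counts.astype(float) / counts.sum()
    return (1.0 - smoothing) * p + smoothing / bins


def estimate_class_distributions(C_train: CorrelationMatrix, labels: Sequence,
                                 n_ref: int | None = None, bins: int = DBC_BINS,
                                 seed: int | None = None) -> dict:
    """Per ordered class pair, the histogram of train-train correlations.

    Self-correlations are excluded.  With ``n_ref`` set (F-DBC), only the
    correlations between reference subsets of the two classes contribute.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(C_train.col_ids):
        raise ValueError("one label per training sample required")
    classes = _class_order(labels)
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} needs at least 2 samples")
    if n_ref is not None:
        refs = select_references(labels, n_ref, seed)
        index = {c: refs[c] for c in classes}
    else:
        index = {c: np.flatnonzero(labels == c) for c in classes}

    dists: dict = {"bins": bins, "classes": classes, "hist": {}}
    for ci in classes:
        for cj in classes:
            rows, cols = index[ci], index[cj]
            block = C_train.entries[np.ix_(rows, cols)]
            keep = np.ones(block.shape, dtype=bool)
            if ci == cj:
                same = rows[:, None] == cols[None, :]
                keep &= ~same
            keep &= np.isfinite(block)
            vals = block[keep]
            if vals.size == 0:
                raise ValueError(f"no defined correlations between classes "
                                 f"{ci!r} and {cj!r}")
            dists["hist"][(ci, cj)] = _histogram(vals, bins)
    return dists


def kl_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback–Leibler distance sum p * ln(p/q) in nats (>= 0)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"bin mismatch: {p.shape} vs {q.shape}")
    support = p > 0
    if (q[support] <= 0).any():
        raise ValueError("q has empty bins on the support of p; smooth first")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def dbc_predict(C_cross: CorrelationMatrix, labels: Sequence,
                distributions: Mapping) -> np.ndarray:
    """Claiming scheme plus weighted Kullback–Leibler decision rule.

    For a test sample x with per-class correlation histograms Q_j: class i
    *claims* x when KL(Q_i || D_ii) < KL(Q_i || D_ij) for every j != i —
    i.e. from class i's own viewpoint, x's correlations to i look
    intra-class rather than inter-class.  x is then assigned among the
    claimants (among all classes when none claims) to the class i whose
    profile minimises S(i) = (1/n_classes) * sum_j KL(Q_j || D_ij); ties
    resolve toward the first class in label order.  The equal pair weights
    make every class contribute to the decision regardless of abundance.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(C_cross.col_ids):
        raise ValueError("one label per training column required")
    classes = distributions["classes"]
    bins = distributions["bins"]
    hist = distributions["hist"]
    class_cols = {c: np.flatnonzero(labels == c) for c in classes}

    preds = np.empty(len(C_cross.row_ids), dtype=object)
    for i, rid in enumerate(C_cross.row_ids):
        q = {}
        for cls in classes:
            vals = C_cross.entries[i, class_cols[cls]]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"test sample {rid!r} has no defined "
                                 f"correlation to class {cls!r}")
            q[cls] = _histogram(vals, bins)
        claimants = [
            ci for ci in classes
            if kl_distance(q[ci], hist[(ci, ci)]) <
            min(kl_distance(q[ci], hist[(ci, cj)]) for cj in classes if cj != ci)
        ]
        candidates = claimants if claimants else list(classes)
        scores = {ci: np.mean([kl_distance(q[cj], hist[(ci, cj)])
                               for cj in classes])
                  for ci in candidates}
        preds[i] = min(candidates, key=lambda c: (scores[c], classes.index(c)))
    return preds


# ---------------------------------------------------------------------------
# estimator-style wrappers, interchangeable with ACFClassifier
# ---------------------------------------------------------------------------

@dataclass
class CorrelationKNN:
    """Brute KNN on pairwise-deletion correlations (estimator interface)."""

    k: int = 5
    weights: str = "uniform"
    oversample: bool = False
    method: str = "pearson"
    min_overlap: int = correlation.DEFAULT_MIN_OVERLAP
    seed: int | None = None

    X_train_: OmicsMatrix | None = field(default=None, repr=False)
    labels_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: OmicsMatrix, labels: Sequence) -> "CorrelationKNN":
        labels = np.asarray(labels, dtype=object)
        if labels.size != X.n_samples:
            raise ValueError("one label per training sample required")
        if self.oversample:
            idx = random_oversample(labels, self.seed)
            self.X_train_ = _subset_dup(X, idx)
            self.labels_ = labels[idx]
        else:
            self.X_train_ = X
            self.labels_ = labels
        return self

    def predict(self, X: OmicsMatrix) -> np.ndarray:
        if self.X_train_ is None:
            raise RuntimeError("classifier is not fitted")
        C = correlation.cross_correlation_matrix(X, self.X_train_, self.method,
                                                 self.min_overlap)
        return knn_predict(C, self.labels_, self.k, self.weights)


def _subset_dup(X: OmicsMatrix, idx: np.ndarray) -> OmicsMatrix:
    """Row subset allowing duplicates (oversampling needs repeated samples)."""
    ids = []
    seen: dict[str, int] = {}
    for i in idx:
        base = X.sample_ids[i]
        n = seen.get(base, 0)
        ids.append(base if n == 0 else f"{base}#dup{n}")
        seen[base] = n + 1
    return OmicsMatrix(X.values[np.asarray(idx, int)], ids, list(X.feature_ids))


@dataclass
class DBCClassifier:
    """Distribution-based classification on correlations (estimator interface).

    ``n_ref`` switches on the fast F-DBC variant.
    """

    n_ref: int | None = None
    bins: int = DBC_BINS
    method: str = "pearson"
    min_overlap: int = correlation.DEFAULT_MIN_OVERLAP
    seed: int | None = None

    X_train_: OmicsMatrix | None = field(default=None, repr=False)
    labels_: np.ndarray | None = field(default=None, repr=False)
    distributions_: dict | None = field(default=None, repr=False)
    ref_index_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: OmicsMatrix, labels: Sequence) -> "DBCClassifier":
        labels = np.asarray(labels, dtype=object)
        if labels.size != X.n_samples:
            raise ValueError("one label per training sample required")
        C = correlation.train_correlation_matrix(X, self.method, self.min_overlap)
        self.distributions_ = estimate_class_distributions(
            C, labels, n_ref=self.n_ref, bins=self.bins, seed=self.seed)
        if self.n_ref is not None:
            refs = select_references(labels, self.n_ref, self.seed)
            self.ref_index_ = np.concatenate(
                [refs[c] for c in self.distributions_["classes"]])
        else:
            self.ref_index_ = np.arange(X.n_samples)
        self.X_train_ = X
        self.labels_ = labels
        return self

    def predict(self, X: OmicsMatrix) -> np.ndarray:
        if self.X_train_ is None:
            raise RuntimeError("classifier is not fitted")
        X_ref = self.X_train_.subset(self.ref_index_)
        C = correlation.cross_correlation_matrix(X, X_ref, self.method,
                                                 self.min_overlap)
        return dbc_predict(C, self.labels_[self.ref_index_], self.distributions_)
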