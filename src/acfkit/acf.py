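"""ACF — classification on class-wise average correlations.

The estimator turns each sample into a tiny feature vector: its average
pairwise correlation (under pairwise deletion) to the training members of
every class, optionally followed by covariate columns.  A tunable baseline
classifier (support-vector classifier, random forest or ridge) is then fit
on that table.  Two variants modify how the averages are formed:

* **F-ACF** estimates each class average from a fixed random subset of
  *reference instances*, which makes prediction cost independent of the
  training-set size.
* **B-ACF** omits correlation entries known to be biased (e.g. pairs of
  samples from the same multiplexed batch) from the averaging.

Self-correlations never contribute to a training sample's own class average:
they carry no information and would bias the estimated block mean upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.svm import SVC

from . import correlation
from .containers import CorrelationMatrix, OmicsMatrix

__all__ = [
    "classwise_averages",
    "select_references",
    "same_batch_mask",
    "make_baseline",
    "ACFClassifier",
]

BASELINE_NAMES = ("svc", "rf", "ridge")


def make_baseline(spec: str, params: Mapping | None = None, seed: int | None = None):
    """Instantiate a named baseline classifier with a parameter dictionary.

    ``spec`` is one of ``svc`` (support-vector classifier), ``rf`` (random
    forest) or ``ridge``; unknown keys are passed through to scikit-learn.
    """
    params = dict(params or {})
    if spec == "svc":
        params.setdefault("random_state", seed)
        return SVC(**params)
    if spec == "rf":
        params.setdefault("random_state", seed)
        params.setdefault("n_jobs", 1)
        return RandomForestClassifier(**params)
    if spec == "ridge":
        return RidgeClassifier(**params)
    raise ValueError(f"unknown baseline classifier {spec!r}; "
                     f"expected one of {BASELINE_NAMES}")


def _class_order(labels: Sequence) -> list:
    seen: dict = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return sorted(seen)


def classwise_averages(C: CorrelationMatrix, labels: Sequence,
                       exclude_self: bool = False,
                       mask: np.ndarray | None = None,
                       covariates: pd.DataFrame | None = None,
                       aggregate: str = "mean",
                       class_order: Sequence | None = None) -> pd.DataFrame:
    """Per target sample, the average correlation to each class of columns.

    Parameters
    ----------
    C
        Correlation matrix, rows = target samples, columns = training
        samples.  Undefined entries are skipped, never zero-filled.
    labels
        Class label per training column.
    exclude_self
        Drop the self-correlation of a row whose id also appears among the
        columns (mandatory when averaging training samples against their own
        training set).
    mask
        Optional boolean matrix aligned to ``C``; True entries are biased and
        omitted from the averaging (B-ACF).
    aggregate
        ``mean`` (default) or ``median``.  The median option is provided for
        outlier-heavy data but is not exercised by the validation studies.

    Raises
    ------
    ValueError
        If any (sample, class) cell has no contributing correlations — an
        empty average is an error, not a silent fill.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(C.col_ids):
        raise ValueError("one label per training column required")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    order = list(class_order) if class_order is not None else _class_order(labels)
    missing_classes = set(labels) - set(order)
    if missing_classes:
        raise ValueError(f"labels contain classes outside class_order: {missing_classes}")

    ok = np.isfinite(C.entries)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != C.entries.shape:
            raise ValueError("bias mask shape does not match correlation matrix")
        ok &= ~mask
    if exclude_self:
        col_pos = {c: j for j, c in enumerate(C.col_ids)}
        for i, rid in enumerate(C.row_ids):
            j = col_pos.get(rid)
            if j is not None:
                ok[i, j] = False

    vals = np.where(ok, C.entries, np.nan)
    out = np.empty((len(C.row_ids), len(order)))
    for k, cls in enumerate(order):
        cols = np.flatnonzero(labels == cls)
        if cols.size == 0:
            raise ValueError(f"class {cls!r} has no training columns")
        block = vals[:, cols]
        counts = ok[:, cols].sum(axis=1)
        if (counts == 0).any():
            i = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(
                f"empty average: sample {C.row_ids[i]!r} has no usable "
                f"correlation to class {cls!r} (all undefined, masked or self)")
        with np.errstate(invalid="ignore"):
            if aggregate == "mean":
                out[:, k] = np.nanmean(block, axis=1)
            else:
                out[:, k] = np.nanmedian(block, axis=1)

    table = pd.DataFrame(out, index=C.row_ids,
                         columns=[f"mu_{cls}" for cls in order])
    table.attrs["class_order"] = order
    if covariates is not None:
        cov = covariates.reindex(table.index)
        if cov.isna().any().any():
            missing = cov.index[cov.isna().any(axis=1)].tolist()
            raise ValueError(f"covariates missing for samples: {missing}")
        table = pd.concat([table, cov], axis=1)
    return table


def select_references(labels: Sequence, n_ref: int, seed: int | None = None
                      ) -> dict[object, np.ndarray]:
    """Uniform random reference subset of size min(n_ref, class size) per class."""
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    refs: dict[object, np.ndarray] = {}
    for cls in _class_order(labels):
        idx = np.flatnonzero(labels == cls)
        take = min(int(n_ref), idx.size)
        refs[cls] = np.sort(rng.choice(idx, size=take, replace=False))
    return refs


def same_batch_mask(batches: Sequence, col_batches: Sequence | None = None
                    ) -> np.ndarray:
    """Bias mask flagging pairs of samples measured in the same batch.

    With one argument, returns the square train-vs-train mask
    (``mask[i, j] = batch_i == batch_j and i != j``; diagonal False).  With
    two arguments, returns the rectangular rows-vs-columns mask for
    test-to-train correlations (no diagonal exemption).
    """
    rows = np.asarray(batches, dtype=object)
    if col_batches is None:
        eq = rows[:, None] == rows[None, :]
        np.fill_diagonal(eq, False)
        return eq
    cols = np.asarray(col_batches, dtype=object)
    return rows[:, None] == cols[None, :]


@dataclass
class ACFClassifier:
    """Average-correlations-as-features classifier.

    Parameters
    ----------
    baseline
        ``svc``/``rf``/``ridge`` or any scikit-learn classifier instance.
    baseline_params
        Parameter dictionary for a named baseline.
    method, min_overlap
        Correlation settings (Pearson or Spearman under pairwise deletion).
    n_ref
        If set, use the F-ACF variant: class averages are estimated against
        ``min(n_ref, class size)`` randomly chosen reference instances only.
    aggregate
        ``mean`` (default) or ``median``.
    seed
        Controls reference sampling and any stochastic baseline.

    Covariates, if given, are appended to the feature table unscaled; users
    of scale-sensitive baselines should standardise them beforehand.  Batch
    ids, if given at fit/predict, activate the B-ACF variant: correlations
    between same-batch samples are omitted from the averages.
    """

    baseline: object = "svc"
    baseline_params: Mapping | None = None
    method: str = "pearson"
    min_overlap: int = correlation.DEFAULT_MIN_OVERLAP
    n_ref: int | None = None
    aggregate: str = "mean"
    seed: int | None = None

    # fitted state
    X_train_: OmicsMatrix | None = field(default=None, repr=False)
    labels_: np.ndarray | None = field(default=None, repr=False)
    classes_: list | None = field(default=None, repr=False)
    references_: dict | None = field(default=None, repr=False)
    train_batches_: np.ndarray | None = field(default=None, repr=False)
    covariate_columns_: list[str] | None = field(default=None, repr=False)
    baseline_: object = field(default=None, repr=False)

    def _make_baseline(self):
        if isinstance(self.baseline, str):
            return make_baseline(self.baseline, self.baseline_params, self.seed)
        from sklearn.base import clone
        return clone(self.baseline)

    def fit(self, X: OmicsMatrix, labels: Sequence,
            covariates: pd.DataFrame | None = None,
            batches: Sequence | None = None) -> "ACFClassifier":
        labels = np.asarray(labels, dtype=object)
        if labels.size != X.n_samples:
            raise ValueError("one label per training sample required")
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("at least 2 classes required")
        small = classes[counts < 2]
        if small.size:
            raise ValueError(f"classes with fewer than 2 samples: {list(small)}")
        self.X_train_ = X
        self.labels_ = labels
        self.classes_ = list(classes)
        self.references_ = (select_references(labels, self.n_ref, self.seed)
                            if self.n_ref is not None else None)
        self.train_batches_ = (np.asarray(batches, dtype=object)
                               if batches is not None else None)

        C = correlation.train_correlation_matrix(X, self.method, self.min_overlap)
        mask = None
        if self.train_batches_ is not None:
            mask = same_batch_mask(self.train_batches_)
        if self.references_ is not None:
            C, labels_sub, mask = self._restrict_to_references(C, mask)
        else:
            labels_sub = labels
        table = classwise_averages(C, labels_sub, exclude_self=True, mask=mask,
                                   covariates=covariates, aggregate=self.aggregate,
                                   class_order=self.classes_)
        self.covariate_columns_ = (list(covariates.columns)
                                   if covariates is not None else [])
        self.baseline_ = self._make_baseline()
        self.baseline_.fit(table.to_numpy(), labels)
        return self

    def _restrict_to_references(self, C: CorrelationMatrix,
                                mask: np.ndarray | None):
        """Keep only reference columns of a correlation matrix."""
        ref_idx = np.concatenate([self.references_[c] for c in self.classes_])
        entries = C.entries[:, ref_idx]
        sub = CorrelationMatrix(entries, list(C.row_ids),
                                [C.col_ids[i] for i in ref_idx],
                                method=C.method, min_overlap=C.min_overlap)
        labels_sub = self.labels_[ref_idx]
        mask_sub = mask[:, ref_idx] if mask is not None else None
        return sub, labels_sub, mask_sub

    def _check_fitted(self) -> None:
        if self.baseline_ is None:
            raise RuntimeError("classifier is not fitted")

    def _train_subset_for_prediction(self) -> tuple[OmicsMatrix, np.ndarray, np.ndarray]:
        """Training samples a prediction must correlate against.

        Under F-ACF only the reference instances are touched, which is what
        makes prediction cost independent of the training-set size.
        """
        if self.references_ is None:
            idx = np.arange(self.X_train_.n_samples)
        else:
            idx = np.concatenate([self.references_[c] for c in self.classes_])
        return self.X_train_.subset(idx), self.labels_[idx], idx

    def transform(self, X: OmicsMatrix, covariates: pd.DataFrame | None = None,
                  batches: Sequence | None = None) -> pd.DataFrame:
        """Class-wise average-correlation feature table for new samples."""
        self._check_fitted()
        X_ref, labels_ref, idx = self._train_subset_for_prediction()
        C = correlation.cross_correlation_matrix(X, X_ref, self.method,
                                                 self.min_overlap)
        mask = None
        if batches is not None:
            if self.train_batches_ is None:
                raise ValueError("batches given at predict but not at fit")
            mask = same_batch_mask(np.asarray(batches, dtype=object),
                                   self.train_batches_[idx])
        exclude_self = bool(set(X.sample_ids) & set(X_ref.sample_ids))
        return classwise_averages(C, labels_ref, exclude_self=exclude_self,
                                  mask=mask, covariates=covariates,
                                  aggregate=self.aggregate,
                                  class_order=self.classes_)

    def predict(self, X: OmicsMatrix, covariates: pd.DataFrame | None = None,
                batches: Sequence | None = None) -> np.ndarray:
        self._check_fitted()
        if self.covariate_columns_ and covariates is None:
            raise ValueError("model was fitted with covariates; none given")
        table = self.transform(X, covariates, batches)
        return np.asarray(self.baseline_.predict(table.to_numpy()))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ACFClassifier":
        model = joblib.load(path)
        if not isinstance(model, ACFClassifier):
            raise TypeError(f"{path} does not contain an ACFClassifier")
        return model
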