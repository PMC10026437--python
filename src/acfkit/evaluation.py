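"""Benchmarking protocol: repeated stratified CV, HPO, and significance.

Classification performance is measured as the macro-averaged F1-score under
repeated stratified k-fold cross-validation (default 10 x 10-fold).  Inside
each fold, tunable classifiers are optimised with a sequential sampler (60
trials by default); each candidate parameter set is scored as the mean
macro-F1 over 10 independently drawn stratified validation splits of 10%
of the fold's training data.  The best candidate is refit on the full
training part of the fold and evaluated once on the held-out fold, which is
never seen by the optimisation.  The whole procedure is repeated with fresh
fold assignments; reported means and standard deviations are taken over the
per-repetition mean scores.

Pairs of methods evaluated on the same splits are compared with the
variance-corrected resampled paired t-test (right-tailed, variance inflated
by n_test/n_train to account for overlapping training sets), with a
Bonferroni factor for multiple comparisons.

All estimators here operate on a *precomputed* full correlation matrix and
index into it per fold, so the expensive all-pairs computation happens once
per dataset rather than once per fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn
from scipy import stats as sp_stats
from sklearn.metrics import f1_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from . import hpo
from .acf import make_baseline
from .baselines import dbc_predict, estimate_class_distributions, knn_predict, \
    random_oversample
from .containers import CorrelationMatrix, OmicsMatrix
from .correlation import train_correlation_matrix

__all__ = [
    "macro_f1",
    "HPOConfig", "CVConfig", "CVResult",
    "make_search_space",
    "repeated_stratified_cv",
    "tune_hyperparameters",
    "corrected_paired_ttest",
    "classwise_importance",
    "ESTIMATORS",
]


def macro_f1(y_true, y_pred, variant: str = "mean") -> float:
    """Macro-averaged F1.

    ``variant='mean'`` (default, the de-facto standard) is the unweighted
    mean of per-class F1 scores; ``variant='harmonic'`` is the harmonic mean
    of the macro-averaged precision and macro-averaged recall.  The two
    coincide for symmetric errors but differ otherwise; classes with zero
    precision+recall score 0.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    labels = sorted(set(y_true) | set(y_pred))
    if variant == "mean":
        return float(f1_score(y_true, y_pred, labels=labels, average="macro",
                              zero_division=0))
    if variant == "harmonic":
        p, r, _, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
        mp, mr = float(np.mean(p)), float(np.mean(r))
        return 0.0 if mp + mr == 0 else 2 * mp * mr / (mp + mr)
    raise ValueError(f"unknown macro-F1 variant {variant!r}")


def _fast_macro_f1(codes_true: np.ndarray, codes_pred: np.ndarray,
                   n_classes: int) -> float:
    """Macro-F1 on integer-encoded labels (hot path of the tuning loop)."""
    cm = np.bincount(codes_true * n_classes + codes_pred,
                     minlength=n_classes * n_classes
                     ).reshape(n_classes, n_classes)
    tp = np.diag(cm).astype(float)
    denom = 2 * tp + cm.sum(axis=0) - tp + cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return float(f1.mean())


def _stratified_holdout(labels_codes: np.ndarray, n_classes: int,
                        fraction: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split into (train, validation) positional indices.

    Every class contributes at least one validation sample and keeps at
    least one training sample.
    """
    val_parts, train_parts = [], []
    for c in range(n_classes):
        idx = np.flatnonzero(labels_codes == c)
        perm = rng.permutation(idx)
        n_val = min(max(1, int(round(fraction * idx.size))), idx.size - 1)
        val_parts.append(perm[:n_val])
        train_parts.append(perm[n_val:])
    return np.concatenate(train_parts), np.concatenate(val_parts)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HPOConfig:
    n_trials: int = 60
    n_validation_sets: int = 10
    validation_fraction: float = 0.10
    sampler: str = "tpe"

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    repetitions: int = 10
    hpo: HPOConfig | None = HPOConfig()
    seed: int | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class CVResult:
    """Per repetition x fold scores plus chosen hyperparameters."""

    scores: pd.DataFrame       # repetition, fold, score, n_train, n_test, params
    per_class: pd.DataFrame    # repetition, fold, class, precision, recall, f1
    estimator: str

    @property
    def fold_scores(self) -> np.ndarray:
        return self.scores["score"].to_numpy()

    @property
    def rep_scores(self) -> np.ndarray:
        """Mean macro-F1 per repetition (the reported unit of replication)."""
        return self.scores.groupby("repetition")["score"].mean().to_numpy()

    @property
    def mean_score(self) -> float:
        return float(self.rep_scores.mean())

    @property
    def sd_score(self) -> float:
        reps = self.rep_scores
        return float(reps.std(ddof=1)) if reps.size > 1 else 0.0

    def per_class_f1(self) -> pd.Series:
        return self.per_class.groupby("class")["f1"].mean()


# ---------------------------------------------------------------------------
# search spaces (bounds as printed in the protocol)
# ---------------------------------------------------------------------------

def make_search_space(kind: str, n_train: int | None = None,
                      n_feature_cols: int | None = None) -> dict:
    """Hyperparameter space for a named estimator kind.

    ``kind`` is ``svc``, ``rf``, ``ridge`` (baseline classifiers on the ACF
    feature table) or ``knn``.  DBC is parameter-free: empty space.
    """
    if kind == "svc":
        return {
            "kernel": hpo.Categorical(("linear", "rbf")),
            "C": hpo.Float(5e-3, 5e2, log=True),
            "gamma": hpo.Categorical(("scale", "auto")),
            "class_weight": hpo.Categorical(("balanced", None)),
        }
    if kind == "rf":
        if n_feature_cols is None:
            raise ValueError("rf space needs n_feature_cols")
        return {
            "n_estimators": hpo.Int(80, 300),
            "max_depth": hpo.Int(2, 40),
            "max_features": hpo.Int(1, max(1, int(n_feature_cols))),
            "class_weight": hpo.Categorical(("balanced", None)),
        }
    if kind == "ridge":
        return {
            "alpha": hpo.Float(1e-3, 1e4, log=True),
            "class_weight": hpo.Categorical(("balanced", None)),
        }
    if kind == "knn":
        if n_train is None:
            raise ValueError("knn space needs n_train")
        return {
            "k": hpo.Int(1, max(1, int(n_train))),
            "weights": hpo.Categorical(("uniform", "distance")),
        }
    if kind == "dbc":
        return {}
    raise ValueError(f"unknown estimator kind {kind!r}")


# ---------------------------------------------------------------------------
# correlation-level estimators (index into one precomputed matrix)
# ---------------------------------------------------------------------------

def _submatrix(C: CorrelationMatrix, rows: np.ndarray, cols: np.ndarray
               ) -> CorrelationMatrix:
    return CorrelationMatrix(
        C.entries[np.ix_(rows, cols)],
        [C.row_ids[i] for i in rows], [C.col_ids[j] for j in cols],
        method=C.method, min_overlap=C.min_overlap)


@dataclass(frozen=True)
class ACFSpec:
    """ACF with a named baseline classifier, optionally with covariates."""

    baseline: str = "svc"
    use_covariates: bool = False
    drop_column: str | None = None  # for variable-importance runs
    fixed_params: Mapping | None = None

    @property
    def name(self) -> str:
        return f"acf-{self.baseline}" + ("+cov" if self.use_covariates else "")

    def space(self, n_train: int, n_classes: int, n_cov: int) -> dict:
        if self.fixed_params is not None:
            return {}
        n_cols = n_classes + (n_cov if self.use_covariates else 0)
        if self.drop_column is not None:
            n_cols -= 1
        return make_search_space(self.baseline, n_train=n_train,
                                 n_feature_cols=n_cols)

    def _features(self, C, labels, train_idx, target_idx, covariates, classes):
        """Average-correlation feature array (plus covariates) in numpy.

        Equivalent to :func:`acfkit.acf.classwise_averages` on the indexed
        submatrix, without per-call DataFrame overhead — this runs thousands
        of times inside the hyperparameter search.
        """
        train_idx = np.asarray(train_idx)
        target_idx = np.asarray(target_idx)
        sub = C.entries[np.ix_(target_idx, train_idx)]
        ok = np.isfinite(sub)
        # exclude self-correlations wherever a target is also a train sample
        pos = np.full(C.entries.shape[0], -1)
        pos[train_idx] = np.arange(train_idx.size)
        tpos = pos[target_idx]
        hit = np.flatnonzero(tpos >= 0)
        ok[hit, tpos[hit]] = False

        class_arr = np.asarray(classes, dtype=object)
        codes = np.searchsorted(class_arr, labels[train_idx])
        ind = np.zeros((train_idx.size, len(classes)))
        ind[np.arange(train_idx.size), codes] = 1.0
        counts = ok @ ind
        if (counts == 0).any():
            i, k = np.argwhere(counts == 0)[0]
            raise ValueError(
                f"empty average: sample {C.row_ids[target_idx[i]]!r} has no "
                f"usable correlation to class {classes[k]!r}")
        feats = (np.where(ok, sub, 0.0) @ ind) / counts
        names = [f"mu_{c}" for c in classes]
        if self.use_covariates and covariates is not None:
            feats = np.hstack([feats, covariates.to_numpy()[target_idx]])
            names += list(covariates.columns)
        if self.drop_column is not None:
            keep = [j for j, n in enumerate(names) if n != self.drop_column]
            if len(keep) == len(names):
                raise ValueError(f"unknown feature column {self.drop_column!r}")
            feats = feats[:, keep]
        return feats

    def fit_predict(self, C, labels, covariates, train_idx, test_idx,
                    params, seed):
        classes = sorted(set(labels[train_idx]))
        use = dict(self.fixed_params) if self.fixed_params is not None else dict(params)
        Xtr = self._features(C, labels, train_idx, train_idx, covariates, classes)
        Xte = self._features(C, labels, train_idx, test_idx, covariates, classes)
        clf = make_baseline(self.baseline, use, seed)
        clf.fit(Xtr, labels[train_idx])
        return np.asarray(clf.predict(Xte))


@dataclass(frozen=True)
class KNNSpec:
    """Brute correlation-KNN, optionally with random oversampling."""

    oversample: bool = False
    fixed_params: Mapping | None = None

    @property
    def name(self) -> str:
        return "knn+ros" if self.oversample else "knn"

    def space(self, n_train: int, n_classes: int, n_cov: int) -> dict:
        if self.fixed_params is not None:
            return {}
        return make_search_space("knn", n_train=n_train)

    def fit_predict(self, C, labels, covariates, train_idx, test_idx,
                    params, seed):
        train_idx = np.asarray(train_idx)
        if self.fixed_params is not None:
            params = dict(self.fixed_params)
        if self.oversample:
            os_idx = random_oversample(labels[train_idx], seed)
            train_idx = train_idx[os_idx]
        k = min(int(params.get("k", 1)), train_idx.size)
        weights = params.get("weights", "uniform")
        entries = C.entries[np.ix_(test_idx, train_idx)]
        return knn_predict(entries, labels[train_idx], k, weights)


@dataclass(frozen=True)
class DBCSpec:
    """Parameter-free distribution-based classification."""

    @property
    def name(self) -> str:
        return "dbc"

    def space(self, n_train: int, n_classes: int, n_cov: int) -> dict:
        return {}

    def fit_predict(self, C, labels, covariates, train_idx, test_idx,
                    params, seed):
        Ctr = _submatrix(C, train_idx, train_idx)
        dists = estimate_class_distributions(Ctr, labels[train_idx])
        Cte = _submatrix(C, test_idx, train_idx)
        return dbc_predict(Cte, labels[train_idx], dists)


ESTIMATORS: dict[str, object] = {
    "acf-svc": ACFSpec("svc"),
    "acf-rf": ACFSpec("rf"),
    "acf-ridge": ACFSpec("ridge"),
    "acf-svc+cov": ACFSpec("svc", use_covariates=True),
    "knn": KNNSpec(False),
    "knn+ros": KNNSpec(True),
    "dbc": DBCSpec(),
}


def _resolve(estimator) -> object:
    if isinstance(estimator, str):
        try:
            return ESTIMATORS[estimator]
        except KeyError:
            raise ValueError(f"unknown estimator {estimator!r}; "
                             f"known: {sorted(ESTIMATORS)}") from None
    return estimator


# ---------------------------------------------------------------------------
# hyperparameter tuning on one fold's training part
# ---------------------------------------------------------------------------

def tune_hyperparameters(spec, C, labels, covariates, train_idx,
                         space: Mapping, config: HPOConfig, seed: int,
                         audit: Callable | None = None
                         ) -> tuple[dict, list[hpo.Trial]]:
    """Search ``space`` by scoring each candidate on random validation splits.

    Each trial draws ``n_validation_sets`` fresh stratified splits of the
    fold's training samples, trains on the remainder, and is assigned the
    mean macro-F1 over the validation parts.  Splits are stratified so every
    class is represented even when tiny.
    """
    train_idx = np.asarray(train_idx)
    split_rng = np.random.default_rng(seed)
    classes = np.asarray(sorted(set(labels[train_idx])), dtype=object)
    n_classes = classes.size
    codes = np.searchsorted(classes, labels[train_idx])

    def objective(params: dict) -> float:
        scores = []
        for _ in range(config.n_validation_sets):
            tr_pos, val_pos = _stratified_holdout(
                codes, n_classes, config.validation_fraction, split_rng)
            sub_tr, sub_val = train_idx[tr_pos], train_idx[val_pos]
            if audit is not None:
                audit(sub_tr, sub_val)
            preds = spec.fit_predict(C, labels, covariates, sub_tr, sub_val,
                                     params, seed)
            scores.append(_fast_macro_f1(codes[val_pos],
                                         np.searchsorted(classes, preds),
                                         n_classes))
        return float(np.mean(scores))

    with sklearn.config_context(assume_finite=True):
        return hpo.tune(objective, space, config.n_trials,
                        sampler=config.sampler, seed=seed)


# ---------------------------------------------------------------------------
# the outer protocol
# ---------------------------------------------------------------------------

def repeated_stratified_cv(estimator, X: OmicsMatrix | None, labels,
                           covariates: pd.DataFrame | None = None,
                           config: CVConfig = CVConfig(),
                           method: str = "pearson", min_overlap: int = 3,
                           C: CorrelationMatrix | None = None,
                           audit: Callable | None = None) -> CVResult:
    """Repeated stratified k-fold CV with per-fold hyperparameter search.

    ``estimator`` is a registry name (``acf-svc``, ``acf-rf``, ``acf-ridge``,
    ``acf-svc+cov``, ``knn``, ``knn+ros``, ``dbc``) or a spec object.  A
    precomputed train correlation matrix ``C`` may be passed to share the
    all-pairs computation across estimators.  ``audit``, if given, is called
    as ``audit(rep, fold, train_idx, test_idx, hpo_train, hpo_val)`` for
    every HPO split — used to prove that held-out folds never leak into the
    tuning procedure.
    """
    spec = _resolve(estimator)
    labels = np.asarray(labels, dtype=object)
    if C is None:
        if X is None:
            raise ValueError("either X or a precomputed correlation matrix is required")
        C = train_correlation_matrix(X, method, min_overlap)
    if labels.size != len(C.col_ids):
        raise ValueError("one label per sample required")
    if covariates is not None:
        covariates = covariates.reindex(C.col_ids)

    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < config.k:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than k={config.k} "
            f"folds; use k <= {counts.min()}")

    master = np.random.SeedSequence(config.seed)
    rep_seqs = master.spawn(config.repetitions)
    score_rows, class_rows = [], []
    n = labels.size
    for rep, rep_seq in enumerate(rep_seqs):
        rep_seed = int(rep_seq.generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=config.k, shuffle=True,
                              random_state=rep_seed)
        fold_seqs = rep_seq.spawn(config.k)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
            fold_seed = int(fold_seqs[fold].generate_state(1)[0] % (2 ** 31))
            space = spec.space(tr.size, len(classes),
                               0 if covariates is None else covariates.shape[1])
            params: dict = {}
            if space and config.hpo is not None:
                fold_audit = None
                if audit is not None:
                    fold_audit = lambda str_, sva, _r=rep, _f=fold, _tr=tr, _te=te: \
                        audit(_r, _f, _tr, _te, str_, sva)
                params, _ = tune_hyperparameters(
                    spec, C, labels, covariates, tr, space, config.hpo,
                    fold_seed, audit=fold_audit)
            elif space:
                # no tuning requested: defaults per dimension midpoint/first
                params = {name: (dim.choices[0] if isinstance(dim, hpo.Categorical)
                                 else dim.from_unit(0.5))
                          for name, dim in space.items()}
            preds = spec.fit_predict(C, labels, covariates, tr, te, params,
                                     fold_seed)
            score = macro_f1(labels[te], preds)
            score_rows.append({
                "repetition": rep, "fold": fold, "score": score,
                "n_train": int(tr.size), "n_test": int(te.size),
                "params": json.dumps(params, default=str, sort_keys=True),
            })
            p, r, f1c, _ = precision_recall_fscore_support(
                labels[te], preds, labels=list(classes), zero_division=0)
            for cls, pc, rc, fc in zip(classes, p, r, f1c):
                class_rows.append({"repetition": rep, "fold": fold,
                                   "class": cls, "precision": float(pc),
                                   "recall": float(rc), "f1": float(fc)})
    return CVResult(pd.DataFrame(score_rows), pd.DataFrame(class_rows),
                    getattr(spec, "name", str(estimator)))


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def corrected_paired_ttest(scores_a, scores_b, n_train: int, n_test: int,
                           n_comparisons: int = 1) -> float:
    """Right-tailed corrected resampled paired t-test (H1: mean a > mean b).

    The naive resampled t-test is anti-conservative because CV training sets
    overlap; the correction inflates the variance term from 1/n to
    1/n + n_test/n_train.  The returned p-value is multiplied by
    ``n_comparisons`` (Bonferroni) and capped at 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must have identical length")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    d = a - b
    n = d.size
    var = float(d.var(ddof=1)) if n > 1 else 0.0
    mean = float(d.mean())
    if var == 0.0:
        p = 1.0 if mean <= 0 else 0.0
    else:
        t = mean / np.sqrt((1.0 / n + n_test / n_train) * var)
        p = float(sp_stats.t.sf(t, df=n - 1))
    return min(1.0, p * int(n_comparisons))


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------

IMPORTANCE_BASELINE_PARAMS = {"C": 100.0, "kernel": "rbf",
                              "class_weight": "balanced"}


def classwise_importance(X: OmicsMatrix | None, labels,
                         covariates: pd.DataFrame | None = None,
                         config: CVConfig = CVConfig(hpo=None),
                         baseline_params: Mapping | None = None,
                         C: CorrelationMatrix | None = None) -> pd.DataFrame:
    """Drop-one-column importance of each ACF feature for each class.

    An unoptimised support-vector baseline (default C=100, rbf kernel,
    balanced class weights) is evaluated with repeated stratified CV on the
    full feature table and on tables with one column withheld; the
    importance of column f for class c is the decrease of the mean per-class
    F1 of c when f is withheld.  Returns classes x feature-columns.
    """
    labels = np.asarray(labels, dtype=object)
    params = dict(baseline_params or IMPORTANCE_BASELINE_PARAMS)
    use_cov = covariates is not None
    if C is None:
        C = train_correlation_matrix(X)
    classes = sorted(set(labels))
    columns = [f"mu_{c}" for c in classes]
    if use_cov:
        columns += list(covariates.columns)
    if len(columns) < 2:
        raise ValueError("importance needs at least 2 feature columns")

    def run(drop: str | None) -> pd.Series:
        spec = ACFSpec("svc", use_covariates=use_cov, drop_column=drop,
                       fixed_params=params)
        res = repeated_stratified_cv(spec, None, labels, covariates,
                                     config=config, C=C)
        return res.per_class_f1()

    full = run(None)
    out = pd.DataFrame(index=pd.Index(classes, name="class"),
                       columns=columns, dtype=float)
    for col in columns:
        reduced = run(col)
        out[col] = (full - reduced).reindex(classes).to_numpy()
    return out
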