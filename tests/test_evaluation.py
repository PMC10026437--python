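"""Evaluation protocol: macro-F1, repeated stratified CV, HPO, significance."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from acfkit import hpo
from acfkit.containers import CorrelationMatrix
from acfkit.correlation import train_correlation_matrix
from acfkit.evaluation import (CVConfig, HPOConfig, classwise_importance,
                               corrected_paired_ttest, macro_f1,
                               make_search_space, repeated_stratified_cv,
                               tune_hyperparameters, KNNSpec,
                               _fast_macro_f1)


class TestMacroF1:
    def test_perfect_predictions(self):
        assert macro_f1(["A", "B", "C"], ["A", "B", "C"]) == 1.0

    def test_hand_computed_asymmetric_case(self):
        # class A: P=1, R=1/2 -> F1=2/3 ; class B: P=2/3, R=1 -> F1=4/5
        score = macro_f1(list("AABB"), list("ABBB"))
        assert score == pytest.approx((2 / 3 + 4 / 5) / 2)

    def test_total_confusion_scores_zero(self):
        assert macro_f1(["A", "B"], ["B", "A"]) == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            macro_f1([], [])

    def test_harmonic_variant_differs_on_asymmetric_errors(self):
        y_true, y_pred = list("AABB"), list("ABBB")
        mp, mr = (1 + 2 / 3) / 2, (0.5 + 1) / 2
        assert macro_f1(y_true, y_pred, variant="harmonic") == \
            pytest.approx(2 * mp * mr / (mp + mr))
        assert macro_f1(y_true, y_pred, variant="harmonic") != \
            pytest.approx(macro_f1(y_true, y_pred))

    def test_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("ABC"), 30)
        y_pred = rng.choice(list("ABC"), 30)
        relabel = {"A": "Z", "B": "Q", "C": "M"}
        assert macro_f1(y_true, y_pred) == pytest.approx(
            macro_f1([relabel[c] for c in y_true],
                     [relabel[c] for c in y_pred]))

    def test_fast_path_agrees_with_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 3, 25)
            p = rng.integers(0, 3, 25)
            classes = np.array(list("ABC"), dtype=object)
            assert _fast_macro_f1(t, p, 3) == pytest.approx(
                macro_f1(classes[t], classes[p]))


class _ConstantSpec:
    """Predicts a fixed label; used for hand-checkable CV scores."""

    name = "constant"

    def __init__(self, label):
        self.label = label

    def space(self, n_train, n_classes, n_cov):
        return {}

    def fit_predict(self, C, labels, covariates, train_idx, test_idx,
                    params, seed):
        return np.array([self.label] * len(test_idx), dtype=object)


def _diag_corr(n):
    ids = [f"s{i}" for i in range(n)]
    return CorrelationMatrix(np.eye(n), ids, ids)


class TestRepeatedStratifiedCV:
    def test_constant_majority_classifier_hand_score(self):
        """8 A vs 2 B, k=2: per fold A has P=4/5, R=1 -> macro-F1 = 4/9."""
        labels = np.array(["A"] * 8 + ["B"] * 2, dtype=object)
        res = repeated_stratified_cv(_ConstantSpec("A"), None, labels,
                                     config=CVConfig(k=2, repetitions=1,
                                                     hpo=None, seed=0),
                                     C=_diag_corr(10))
        assert res.mean_score == pytest.approx(4 / 9)
        per_class = res.per_class_f1()
        assert per_class["A"] == pytest.approx(8 / 9)
        assert per_class["B"] == 0.0

    def test_fold_class_proportions_are_preserved(self, noisy_dataset):
        ds = noisy_dataset
        labels = ds.labels.to_numpy()
        seen = []

        class Probe(_ConstantSpec):
            def fit_predict(self, C, labels_, cov, tr, te, params, seed):
                seen.append(te)
                return labels_[te]

        repeated_stratified_cv(Probe("A"), None, labels,
                               config=CVConfig(k=3, repetitions=1, hpo=None,
                                               seed=0),
                               C=_diag_corr(labels.size))
        n = labels.size
        for te in seen:
            for cls in set(labels):
                frac_global = (labels == cls).sum() / n
                in_fold = (labels[te] == cls).sum()
                assert abs(in_fold - frac_global * te.size) <= 1

    def test_result_has_k_times_repetitions_scores(self, noisy_dataset):
        labels = noisy_dataset.labels.to_numpy()
        res = repeated_stratified_cv(_ConstantSpec("A"), None, labels,
                                     config=CVConfig(k=4, repetitions=3,
                                                     hpo=None, seed=1),
                                     C=_diag_corr(labels.size))
        assert len(res.scores) == 12
        assert res.rep_scores.shape == (3,)

    def test_class_smaller_than_k_raises_with_suggestion(self):
        labels = np.array(["A"] * 9 + ["B"] * 3, dtype=object)
        with pytest.raises(ValueError, match="use k <= 3"):
            repeated_stratified_cv(_ConstantSpec("A"), None, labels,
                                   config=CVConfig(k=5, repetitions=1, hpo=None),
                                   C=_diag_corr(12))

    def test_hpo_never_touches_the_held_out_fold(self, noisy_dataset):
        """Leakage audit: every tuning split stays inside the training part."""
        ds = noisy_dataset
        labels = ds.labels.to_numpy()
        C = train_correlation_matrix(ds.X)
        violations = []
        calls = []

        def audit(rep, fold, tr, te, hpo_tr, hpo_val):
            calls.append(1)
            test_set = set(te)
            if test_set & (set(hpo_tr) | set(hpo_val)):
                violations.append((rep, fold))
            if set(hpo_tr) & set(hpo_val):
                violations.append(("overlap", rep, fold))

        repeated_stratified_cv(
            "acf-ridge", None, labels,
            config=CVConfig(k=3, repetitions=1,
                            hpo=HPOConfig(n_trials=4, n_validation_sets=3),
                            seed=0),
            C=C, audit=audit)
        assert calls and not violations

    def test_identical_seeds_reproduce_scores(self, noisy_dataset):
        labels = noisy_dataset.labels.to_numpy()
        C = train_correlation_matrix(noisy_dataset.X)
        cfg = CVConfig(k=3, repetitions=1,
                       hpo=HPOConfig(n_trials=3, n_validation_sets=2), seed=5)
        a = repeated_stratified_cv("acf-svc", None, labels, config=cfg, C=C)
        b = repeated_stratified_cv("acf-svc", None, labels, config=cfg, C=C)
        assert np.array_equal(a.fold_scores, b.fold_scores)
        assert a.scores["params"].tolist() == b.scores["params"].tolist()


class TestSearchSpaces:
    def test_printed_bounds(self):
        svc = make_search_space("svc")
        assert (svc["C"].low, svc["C"].high, svc["C"].log) == (5e-3, 5e2, True)
        rf = make_search_space("rf", n_feature_cols=4)
        assert (rf["n_estimators"].low, rf["n_estimators"].high) == (80, 300)
        assert (rf["max_depth"].low, rf["max_depth"].high) == (2, 40)
        ridge = make_search_space("ridge")
        assert (ridge["alpha"].low, ridge["alpha"].high) == (1e-3, 1e4)
        knn = make_search_space("knn", n_train=135)
        assert (knn["k"].low, knn["k"].high) == (1, 135)

    def test_dbc_space_is_empty(self):
        assert make_search_space("dbc") == {}


class TestTuneHyperparameters:
    def _setup(self, noisy_dataset):
        labels = noisy_dataset.labels.to_numpy()
        C = train_correlation_matrix(noisy_dataset.X)
        return C, labels, np.arange(labels.size)

    def test_single_point_space_returns_that_point(self, noisy_dataset):
        C, labels, tr = self._setup(noisy_dataset)
        space = {"k": hpo.Categorical((3,)), "weights": hpo.Categorical(("uniform",))}
        best, trials = tune_hyperparameters(
            KNNSpec(), C, labels, None, tr, space,
            HPOConfig(n_trials=2, n_validation_sets=2), seed=0)
        assert best == {"k": 3, "weights": "uniform"}

    def test_winning_configuration_is_found_exhaustively(self, noisy_dataset):
        C, labels, tr = self._setup(noisy_dataset)
        # k=1 separates the noisy data far better than k=n_train
        space = {"k": hpo.Categorical((1, tr.size - 10)),
                 "weights": hpo.Categorical(("uniform",))}
        best, _ = tune_hyperparameters(
            KNNSpec(), C, labels, None, tr, space,
            HPOConfig(n_trials=8, n_validation_sets=4), seed=1)
        assert best["k"] == 1

    def test_deterministic_trial_sequence(self, noisy_dataset):
        C, labels, tr = self._setup(noisy_dataset)
        space = make_search_space("knn", n_train=tr.size)
        cfg = HPOConfig(n_trials=6, n_validation_sets=2)
        b1, t1 = tune_hyperparameters(KNNSpec(), C, labels, None, tr, space,
                                      cfg, seed=7)
        b2, t2 = tune_hyperparameters(KNNSpec(), C, labels, None, tr, space,
                                      cfg, seed=7)
        assert b1 == b2
        assert [t.params for t in t1] == [t.params for t in t2]
        assert [t.score for t in t1] == [t.score for t in t2]

    def test_failing_trials_are_logged_not_fatal(self):
        calls = {"n": 0}

        def objective(params):
            calls["n"] += 1
            if params["x"] == "bad":
                raise RuntimeError("boom")
            return 0.5

        best, trials = hpo.tune(objective, {"x": hpo.Categorical(("bad", "ok"))},
                                n_trials=10, seed=0)
        assert best == {"x": "ok"}
        assert any(t.error for t in trials)


class TestCorrectedPairedTTest:
    def test_identical_scores_give_p_one_by_convention(self):
        p = corrected_paired_ttest([0.8, 0.9], [0.8, 0.9], 90, 10)
        assert p == 1.0

    def test_zero_mean_difference_with_variance_gives_half(self):
        a = np.array([0.8, 0.9, 0.7, 0.6])
        b = a[::-1]
        assert corrected_paired_ttest(a, b, 90, 10) == pytest.approx(0.5)

    def test_correction_shrinks_the_t_statistic(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.uniform(0.5, 1.0, 10)
            b = rng.uniform(0.5, 1.0, 10)
            d = a - b
            if d.var(ddof=1) == 0:
                continue
            t_std = d.mean() / np.sqrt(d.var(ddof=1) / d.size)
            t_corr = d.mean() / np.sqrt((1 / d.size + 10 / 90) * d.var(ddof=1))
            assert abs(t_corr) < abs(t_std)
            p = corrected_paired_ttest(a, b, 90, 10)
            assert p == pytest.approx(float(sp_stats.t.sf(t_corr, df=9)))

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.5, 1.0, 8)
        b = a + rng.normal(0, 0.05, 8)
        p1 = corrected_paired_ttest(a, b, 90, 10, n_comparisons=1)
        p10 = corrected_paired_ttest(a, b, 90, 10, n_comparisons=10)
        assert p10 == pytest.approx(min(1.0, 10 * p1))


class TestClasswiseImportance:
    def _cross_correlation_toy(self):
        """Classes A and B separable only through their correlation to C."""
        rng = np.random.default_rng(2)
        sizes = {"A": 12, "B": 12, "C": 12}
        labels = np.array(sum([[c] * n for c, n in sizes.items()], []),
                          dtype=object)
        n = labels.size
        means = {("A", "A"): 0.5, ("A", "B"): 0.5, ("B", "B"): 0.5,
                 ("A", "C"): 0.2, ("B", "C"): 0.4, ("C", "C"): 0.5}
        entries = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                key = tuple(sorted((labels[i], labels[j])))
                entries[i, j] = means[key] + rng.normal(0, 0.01)
        entries = (entries + entries.T) / 2
        np.fill_diagonal(entries, 1.0)
        ids = [f"s{i}" for i in range(n)]
        return CorrelationMatrix(np.clip(entries, -1, 1), ids, ids), labels

    def test_discriminative_cross_correlation_has_positive_importance(self):
        C, labels = self._cross_correlation_toy()
        imp = classwise_importance(None, labels,
                                   config=CVConfig(k=3, repetitions=2,
                                                   hpo=None, seed=0),
                                   C=C)
        assert imp.shape == (3, 3)
        assert imp.loc["A", "mu_C"] > 0.1
        assert imp.loc["B", "mu_C"] > 0.1

    def test_constant_covariate_has_negligible_importance(self, noisy_dataset):
        ds = noisy_dataset
        labels = ds.labels.to_numpy()
        cov = pd.DataFrame({"dummy": np.ones(labels.size)},
                           index=ds.X.sample_ids)
        # fix gamma numerically: the default "scale" re-normalises the rbf
        # width per feature count, which is not the property under test
        imp = classwise_importance(ds.X, labels, covariates=cov,
                                   config=CVConfig(k=3, repetitions=2,
                                                   hpo=None, seed=0),
                                   baseline_params={"C": 100.0, "kernel": "rbf",
                                                    "class_weight": "balanced",
                                                    "gamma": 1.0})
        assert imp["dummy"].abs().max() < 0.05
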