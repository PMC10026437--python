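"""Data-generating process: centers, noise scaling, missingness, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from acfkit.containers import CorrelationMatrix
from acfkit.correlation import train_correlation_matrix
from acfkit.simulate import (DEFAULT_CENTER_CORRELATION, BlockStats,
                             CovariateSpec, SimulationConfig,
                             block_stats, calibrate_missing_fraction,
                             correlated_centers, generate_dataset,
                             relative_noise, residual_normality)
from dataclasses import replace


class TestCorrelatedCenters:
    def test_identity_target_gives_uncorrelated_centers(self):
        centers = correlated_centers(np.eye(3), 10_000, seed=0)
        emp = np.corrcoef(centers)
        off = emp[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_default_target_reached_at_high_dimension(self):
        centers = correlated_centers(DEFAULT_CENTER_CORRELATION, 10_000, seed=1)
        emp = np.corrcoef(centers)
        for (i, j), target in [((0, 1), 0.9), ((1, 2), 0.8), ((0, 2), 0.6)]:
            assert emp[i, j] == pytest.approx(target, abs=0.03)

    def test_non_positive_definite_matrix_raises(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            correlated_centers(bad, 100)

    def test_two_features_is_a_valid_boundary(self):
        centers = correlated_centers(DEFAULT_CENTER_CORRELATION, 2, seed=0)
        assert centers.shape == (3, 2)
        assert np.isfinite(centers).all()


class TestGenerateDataset:
    def test_zero_noise_samples_duplicate_their_center(self):
        cfg = SimulationConfig(n_features=200, sigma_feature=0.0,
                               class_sizes=(3, 3, 3), covariate=None, seed=0)
        ds = generate_dataset(cfg)
        assert np.allclose(ds.X.values[0], ds.X.values[1])
        C = train_correlation_matrix(ds.X)
        assert C.entries[0, 1] == pytest.approx(1.0)

    def test_observed_missing_fraction_matches_request(self):
        cfg = SimulationConfig(n_features=10_000, class_sizes=(10, 10, 10),
                               missing_fraction=0.3, covariate=None, seed=4)
        ds = generate_dataset(cfg)
        assert ds.X.missing_mask.mean() == pytest.approx(0.30, abs=0.01)

    def test_class_sizes_and_label_alignment(self):
        cfg = SimulationConfig(n_features=50, class_sizes=(4, 2, 6),
                               covariate=None, seed=0)
        ds = generate_dataset(cfg)
        assert ds.labels.value_counts().to_dict() == {"C": 6, "A": 4, "B": 2}

    def test_covariate_means_near_class_centers(self):
        spec = CovariateSpec(centers=(0.15, 0.2, 0.25), sd=0.015)
        cfg = SimulationConfig(n_features=50, class_sizes=(60, 60, 60),
                               covariate=spec, seed=8)
        ds = generate_dataset(cfg)
        cov = ds.covariate.iloc[:, 0]
        se = 0.015 / np.sqrt(60)
        for cls, center in zip("ABC", spec.centers):
            mean = cov[ds.labels == cls].mean()
            assert abs(mean - center) < 3 * se

    def test_bitwise_reproducible_under_seed(self):
        cfg = SimulationConfig(n_features=300, class_sizes=(5, 5, 5),
                               missing_fraction=0.2, seed=99)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(a.X.values, b.X.values, equal_nan=True)
        assert (a.covariate == b.covariate).all().all()


class TestBlockStats:
    def test_toy_inter_block_mean(self, toy_corr, toy_labels):
        stats = block_stats(toy_corr, toy_labels)
        assert stats.mean("A", "B") == pytest.approx(0.25)

    def test_zero_noise_blocks_have_zero_sd(self):
        cfg = SimulationConfig(n_features=300, sigma_feature=0.0,
                               class_sizes=(4, 4, 4), covariate=None, seed=1)
        ds = generate_dataset(cfg)
        stats = block_stats(train_correlation_matrix(ds.X),
                            ds.labels.to_numpy())
        assert stats.table["sd"].max() < 1e-9

    def test_sd_grows_with_missing_fraction(self):
        """More missingness -> noisier correlations, in >= 9/10 paired draws."""
        wins = 0
        for rep in range(10):
            base = SimulationConfig(n_features=2000, class_sizes=(10, 10, 10),
                                    covariate=None, seed=1000 + rep)
            lo = generate_dataset(replace(base, missing_fraction=0.1))
            hi = generate_dataset(replace(base, missing_fraction=0.4))
            sd_lo = block_stats(train_correlation_matrix(lo.X),
                                lo.labels.to_numpy()).sigma
            sd_hi = block_stats(train_correlation_matrix(hi.X),
                                hi.labels.to_numpy()).sigma
            wins += sd_hi > sd_lo
        assert wins >= 9


class TestRelativeNoise:
    def _stats(self, sigma):
        table = pd.DataFrame(
            [{"class_i": "A", "class_j": "A", "mean": 0.2, "sd": sigma, "count": 10},
             {"class_i": "A", "class_j": "B", "mean": 0.18, "sd": sigma, "count": 10},
             {"class_i": "B", "class_j": "B", "mean": 0.2, "sd": sigma, "count": 10}],
        ).set_index(["class_i", "class_j"])
        return BlockStats(table, ["A", "B"])

    def test_zero_noise_gives_zero(self):
        assert relative_noise(self._stats(0.0)) == 0.0

    def test_printed_formula(self):
        assert relative_noise(self._stats(0.05), "A", "B") == pytest.approx(2.5)

    def test_zero_gap_raises(self):
        table = pd.DataFrame(
            [{"class_i": "A", "class_j": "A", "mean": 0.2, "sd": 0.1, "count": 5},
             {"class_i": "A", "class_j": "B", "mean": 0.2, "sd": 0.1, "count": 5},
             {"class_i": "B", "class_j": "B", "mean": 0.2, "sd": 0.1, "count": 5}],
        ).set_index(["class_i", "class_j"])
        with pytest.raises(ValueError, match="undefined"):
            relative_noise(BlockStats(table, ["A", "B"]), "A", "B")


class TestCalibration:
    BASE = SimulationConfig(n_features=4000, class_sizes=(20, 20, 20),
                            covariate=None, seed=5)

    def test_zero_target_needs_no_missingness(self):
        frac = calibrate_missing_fraction(self.BASE, 0.0, seed=5)
        assert frac == 0.0

    def test_fraction_increases_with_target(self):
        fracs = [calibrate_missing_fraction(self.BASE, t, seed=5)
                 for t in (1.0, 1.8, 2.6)]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_unachievable_target_raises(self):
        with pytest.raises(ValueError, match="not achievable|did not converge"):
            calibrate_missing_fraction(self.BASE, 500.0, seed=5, tolerance=1.0)

    def test_calibrated_noise_transfers_to_fresh_seeds(self):
        cfg = SimulationConfig(n_features=10_000, class_sizes=(30, 30, 30),
                               covariate=None, seed=17)
        frac = calibrate_missing_fraction(cfg, 2.9, seed=17)
        fresh = generate_dataset(replace(cfg, missing_fraction=frac, seed=18))
        sig = relative_noise(block_stats(train_correlation_matrix(fresh.X),
                                         fresh.labels.to_numpy()))
        assert sig == pytest.approx(2.9, abs=0.3)


class TestResidualNormality:
    def _gaussian_block_matrix(self, rng, n=25, sd=0.01):
        entries = rng.normal(0.2, sd, size=(n, n))
        entries = (entries + entries.T) / 2
        np.fill_diagonal(entries, 1.0)
        ids = [f"s{i}" for i in range(n)]
        return CorrelationMatrix(np.clip(entries, -1, 1), ids, ids)

    def test_calibrated_rejection_rate_on_gaussian_residuals(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 200
        for _ in range(reps):
            C = self._gaussian_block_matrix(rng)
            p = residual_normality(C, ["A"] * 25).iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_skewed_residuals_are_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 50
        for _ in range(reps):
            n = 25
            entries = 0.1 + rng.exponential(0.05, size=(n, n))
            entries = (entries + entries.T) / 2
            np.fill_diagonal(entries, 1.0)
            ids = [f"s{i}" for i in range(n)]
            C = CorrelationMatrix(np.clip(entries, -1, 1), ids, ids)
            hits += residual_normality(C, ["A"] * n).iloc[0] < 0.05
        assert hits / reps > 0.9

    def test_small_block_raises(self, toy_corr, toy_labels):
        with pytest.raises(ValueError, match="entries"):
            residual_normality(toy_corr, toy_labels)

    def test_near_boundary_correlations_break_normality(self):
        """Tiny feature noise pushes correlations toward 1, skewing residuals."""
        rejected = 0
        for rep in range(3):
            cfg = SimulationConfig(n_features=2000, sigma_feature=0.1,
                                   class_sizes=(15, 15, 15),
                                   missing_fraction=0.5, covariate=None,
                                   seed=50 + rep)
            ds = generate_dataset(cfg)
            pvals = residual_normality(train_correlation_matrix(ds.X),
                                       ds.labels.to_numpy())
            rejected += (pvals < 0.05).any()
        assert rejected >= 2
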