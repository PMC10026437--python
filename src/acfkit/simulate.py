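"""Synthetic datasets with block-structured correlation matrices.

The generator draws class centers whose pairwise Pearson correlations follow
a user-specified positive-definite matrix (via a Cholesky factor applied to
i.i.d. standard-normal feature draws), places each observation around its
class center with i.i.d. Gaussian feature noise of standard deviation
``sigma_feature``, and finally deletes a fixed expected fraction of entries
completely at random (MCAR).  An optional scalar covariate is drawn from a
Gaussian around class-specific centers and kept out of the correlation
computation (a side channel for the classifier only).

Two facts about the resulting sample-sample correlation matrix drive the
diagnostics in this module:

* Feature noise attenuates every block mean by the factor
  ``1 / (1 + sigma_feature**2)`` (unit-variance centers plus independent
  noise of variance sigma_feature**2), without changing block SDs.
* Missingness leaves block means unchanged but inflates the block SD, since
  each pairwise correlation is estimated from a random feature subset.  The
  ratio sigma_rel = sigma / (mu_AA - mu_AB) summarises how noisy the matrix
  is relative to the block contrast that separates the two closest classes.

The default configuration is three classes of 70/30/50 samples over 10,000
features with a center-correlation matrix whose first two classes are nearly
collinear (0.9) but differ strongly in their correlation to the third class
(0.6 vs 0.8) — the minimal setting in which a *cross*-correlation carries
the discriminative signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import correlation
from .containers import CorrelationMatrix, OmicsMatrix

__all__ = [
    "DEFAULT_CENTER_CORRELATION",
    "CovariateSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "BlockStats",
    "correlated_centers",
    "generate_dataset",
    "block_stats",
    "relative_noise",
    "calibrate_missing_fraction",
    "residual_normality",
]

#: Center correlations of the default three-class setting: classes A and B
#: are closely correlated (0.9) yet separable through their different
#: correlation to class C (0.6 vs 0.8).
DEFAULT_CENTER_CORRELATION = np.array([
    [1.0, 0.9, 0.6],
    [0.9, 1.0, 0.8],
    [0.6, 0.8, 1.0],
])


@dataclass(frozen=True)
class CovariateSpec:
    """Gaussian per-class covariate: one center per class, common SD."""

    centers: tuple[float, ...] = (0.15, 0.2, 0.25)
    sd: float = 0.015
    name: str = "covariate"


@dataclass(frozen=True)
class SimulationConfig:
    n_features: int = 10_000
    c_centers: np.ndarray = field(default_factory=lambda: DEFAULT_CENTER_CORRELATION.copy())
    sigma_feature: float = 2.0
    class_sizes: tuple[int, ...] = (70, 30, 50)
    missing_fraction: float = 0.0
    covariate: CovariateSpec | None = CovariateSpec()
    class_names: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.c_centers, dtype=float)
        object.__setattr__(self, "c_centers", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("c_centers must be square")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("c_centers must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("c_centers must have unit diagonal")
        if len(self.class_sizes) != c.shape[0]:
            raise ValueError("one class size per row of c_centers required")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        names = self.class_names
        if names is None:
            names = tuple(chr(ord("A") + i) for i in range(c.shape[0]))
        if len(names) != c.shape[0]:
            raise ValueError("one class name per class required")
        object.__setattr__(self, "class_names", tuple(names))
        if self.covariate is not None and \
                len(self.covariate.centers) != c.shape[0]:
            raise ValueError("one covariate center per class required")

    @property
    def n_classes(self) -> int:
        return self.c_centers.shape[0]

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes))


@dataclass
class SimulatedDataset:
    X: OmicsMatrix
    labels: pd.Series
    covariate: pd.DataFrame | None
    centers: np.ndarray
    config: SimulationConfig


def correlated_centers(c_centers: np.ndarray, n_features: int,
                       seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Class centers (classes x features) with the requested correlations.

    A Cholesky factor L of the target matrix applied to an i.i.d. standard
    normal draw Z gives centers L @ Z whose empirical Pearson correlations
    converge to the target as n_features grows (at n_features = 2 the
    procedure still runs but the empirical correlations are essentially
    arbitrary).  Features have unit variance.
    """
    c = np.asarray(c_centers, dtype=float)
    try:
        L = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "c_centers is not positive definite (Cholesky factorisation "
            f"failed: {exc})") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((c.shape[0], int(n_features)))
    return L @ z


def generate_dataset(config: SimulationConfig,
                     centers: np.ndarray | None = None) -> SimulatedDataset:
    """Draw one dataset from the generating process (reproducible by seed).

    Passing ``centers`` (e.g. from a previous draw's ``SimulatedDataset``)
    reuses existing class centers, so a fresh cohort is sampled from the
    same population — the natural way to create an independent test set.
    """
    rng = np.random.default_rng(config.seed)
    if centers is None:
        centers = correlated_centers(config.c_centers, config.n_features, rng)
    else:
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (config.n_classes, config.n_features):
            raise ValueError(
                f"centers shape {centers.shape} does not match "
                f"{(config.n_classes, config.n_features)}")
    n = config.n_samples
    values = np.empty((n, config.n_features))
    labels = np.empty(n, dtype=object)
    row = 0
    for k, (name, size) in enumerate(zip(config.class_names, config.class_sizes)):
        noise = rng.standard_normal((size, config.n_features)) * config.sigma_feature
        values[row:row + size] = centers[k] + noise
        labels[row:row + size] = name
        row += size
    if config.missing_fraction > 0:
        drop = rng.random((n, config.n_features)) < config.missing_fraction
        values[drop] = np.nan
    sample_ids = [f"s{i:04d}" for i in range(n)]
    X = OmicsMatrix(values, sample_ids, [f"f{j}" for j in range(config.n_features)])
    label_series = pd.Series(labels, index=sample_ids, name="label")

    covariate = None
    if config.covariate is not None:
        spec = config.covariate
        center_by_class = dict(zip(config.class_names, spec.centers))
        draws = rng.normal([center_by_class[l] for l in labels], spec.sd)
        covariate = pd.DataFrame({spec.name: draws}, index=sample_ids)
    return SimulatedDataset(X, label_series, covariate, centers, config)


# ---------------------------------------------------------------------------
# diagnostics on correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class BlockStats:
    """Mean and SD of each class-pair block of a correlation matrix.

    ``table`` is indexed by (class_i, class_j) with columns mean/sd/count.
    ``sigma`` is the average of the per-block SDs; on data from this
    generator the block SDs are all approximately equal, so their mean is
    the natural single noise scale.
    """

    table: pd.DataFrame
    classes: list

    def mean(self, a, b) -> float:
        return float(self.table.loc[(a, b), "mean"])

    def sd(self, a, b) -> float:
        return float(self.table.loc[(a, b), "sd"])

    @property
    def sigma(self) -> float:
        return float(self.table["sd"].mean())


def block_stats(C: CorrelationMatrix, labels: Sequence) -> BlockStats:
    """Per class pair, mean/SD over defined, non-self correlations."""
    if not C.is_square:
        raise ValueError("block statistics need a square train correlation matrix")
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(C.col_ids):
        raise ValueError("one label per sample required")
    classes = sorted(set(labels))
    rows = []
    for i, ci in enumerate(classes):
        for cj in classes[i:]:
            ri = np.flatnonzero(labels == ci)
            rj = np.flatnonzero(labels == cj)
            block = C.entries[np.ix_(ri, rj)]
            keep = np.isfinite(block)
            if ci == cj:
                keep &= ~np.eye(len(ri), dtype=bool)
                iu = np.triu_indices(len(ri), k=1)
                sel = np.zeros_like(keep)
                sel[iu] = True
                keep &= sel  # each unordered pair once
            vals = block[keep]
            if vals.size == 0:
                raise ValueError(f"empty correlation block ({ci}, {cj})")
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append({"class_i": ci, "class_j": cj,
                         "mean": float(vals.mean()), "sd": sd,
                         "count": int(vals.size)})
    table = pd.DataFrame(rows).set_index(["class_i", "class_j"])
    return BlockStats(table, classes)


def _default_pair(stats_: BlockStats) -> tuple:
    """The two most-correlated distinct classes (largest inter-block mean)."""
    inter = stats_.table[[i != j for i, j in stats_.table.index]]
    a, b = inter["mean"].idxmax()
    return a, b


def relative_noise(stats_: BlockStats, class_a=None, class_b=None) -> float:
    """sigma / (mu_AA - mu_AB): correlation noise relative to the A-B contrast."""
    if class_a is None or class_b is None:
        class_a, class_b = _default_pair(stats_)
    mu_aa = stats_.mean(class_a, class_a)
    try:
        mu_ab = stats_.mean(class_a, class_b)
    except KeyError:
        mu_ab = stats_.mean(class_b, class_a)
    gap = mu_aa - mu_ab
    if gap == 0:
        raise ValueError(f"mu({class_a},{class_a}) equals mu({class_a},{class_b}); "
                         "relative noise is undefined")
    return stats_.sigma / gap


def measured_sigma_rel(config: SimulationConfig, seed=None,
                       method: str = "pearson") -> float:
    """Generate one dataset under ``config`` and measure its sigma_rel."""
    cfg = config if seed is None else replace(config, seed=seed)
    ds = generate_dataset(cfg)
    C = correlation.train_correlation_matrix(ds.X, method=method)
    return relative_noise(block_stats(C, ds.labels.to_numpy()))


def calibrate_missing_fraction(config: SimulationConfig, target_sigma_rel: float,
                               tolerance: float = 0.1,
                               seed: int | None = None,
                               max_fraction: float = 0.995,
                               max_iter: int = 40,
                               n_pilots: int = 3) -> float:
    """Missing fraction whose realised sigma_rel hits the target (bisection).

    sigma_rel grows monotonically with the missing fraction (fewer shared
    features per pair means noisier correlation estimates), so a bisection
    on the fraction, measuring sigma_rel on pilot datasets of the full
    configured size at each step, converges quickly.  Each step averages
    ``n_pilots`` pilot datasets with fixed seeds: a single realisation's
    sigma_rel carries the sampling error of its center draw (the A-B block
    gap at the default centers is small), and averaging keeps that bias out
    of the returned fraction.  The search sees a deterministic curve.
    """
    if target_sigma_rel < 0:
        raise ValueError("target sigma_rel must be non-negative")
    pilot_seed = seed if seed is not None else config.seed
    if n_pilots <= 1:
        # single pilot: reuse the seed as-is, so calibrating "the dataset
        # that will be generated with this seed" is exact
        pilot_seeds = [pilot_seed]
    else:
        pilot_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                       for s in np.random.SeedSequence(pilot_seed).spawn(n_pilots)]
    base = replace(config, missing_fraction=0.0)

    def measure(frac: float) -> float:
        """sigma_rel at a fraction; NaN once the block structure breaks down.

        Past extreme missingness the pairwise overlaps shrink to a handful
        of features, the A-A vs A-B mean gap collapses or inverts, and
        sigma_rel stops being meaningful; such values (and negative ones)
        are treated as beyond any positive target.
        """
        vals = []
        for ps in pilot_seeds:
            try:
                vals.append(measured_sigma_rel(
                    replace(base, missing_fraction=frac), seed=ps))
            except ValueError:
                return float("nan")
        val = float(np.mean(vals))
        return val if val > 0 else float("nan")

    lo_val = measure(0.0)
    if not np.isfinite(lo_val):
        raise ValueError("sigma_rel is undefined even without missing values; "
                         "check the configuration")
    if target_sigma_rel <= lo_val + tolerance:
        return 0.0

    # expand the upper bracket by repeatedly halving the retained fraction
    lo, hi = 0.0, 0.5
    hi_val = measure(hi)
    while np.isfinite(hi_val) and hi_val < target_sigma_rel and hi < max_fraction:
        lo = hi
        hi = min(max_fraction, 1.0 - (1.0 - hi) / 2.0)
        hi_val = measure(hi)
        if hi >= max_fraction and np.isfinite(hi_val) and hi_val < target_sigma_rel:
            raise ValueError(
                f"target sigma_rel={target_sigma_rel} not achievable: fraction "
                f"{hi} only reaches sigma_rel={hi_val:.3f} (at 0.0: {lo_val:.3f})")

    for _ in range(max_iter):
        mid = (lo + hi) / 2
        val = measure(mid)
        if np.isfinite(val) and abs(val - target_sigma_rel) <= tolerance:
            return mid
        if np.isfinite(val) and val < target_sigma_rel:
            lo = mid
        else:  # overshoot or breakdown: come back down
            hi = mid
        if hi - lo < 1e-4:
            break
    raise ValueError(
        f"calibration did not converge to sigma_rel={target_sigma_rel} "
        f"within tolerance {tolerance}; bracket [{lo:.4f}, {hi:.4f}]")


def residual_normality(C: CorrelationMatrix, labels: Sequence,
                       min_block: int = 20) -> pd.Series:
    """D'Agostino–Pearson omnibus p-value per block's mean-centred residuals.

    Low average correlations leave room for symmetric Gaussian noise; blocks
    whose means sit near the correlation bound +/-1 are expected to fail the
    test because the noise there cannot be symmetric.
    """
    stats_ = block_stats(C, labels)
    labels = np.asarray(labels, dtype=object)
    pvals = {}
    for (ci, cj), row in stats_.table.iterrows():
        if row["count"] < min_block:
            raise ValueError(f"block ({ci}, {cj}) has only {int(row['count'])} "
                             f"entries; need >= {min_block} for the omnibus test")
        ri = np.flatnonzero(labels == ci)
        rj = np.flatnonzero(labels == cj)
        block = C.entries[np.ix_(ri, rj)]
        keep = np.isfinite(block)
        if ci == cj:
            iu = np.triu_indices(len(ri), k=1)
            sel = np.zeros_like(keep)
            sel[iu] = True
            keep &= sel
        residuals = block[keep] - row["mean"]
        pvals[(ci, cj)] = float(stats.normaltest(residuals).pvalue)
    return pd.Series(pvals, name="dagostino_pearson_p")
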