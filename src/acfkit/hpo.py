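"""Sequential hyperparameter search with a tree-structured Parzen estimator.

The search space is a flat dictionary of named dimensions (categorical,
float, log-float or integer ranges).  The TPE sampler models each dimension
independently: after a random start-up phase, observed trials are split into
a "good" top quantile and the rest, each side is modelled by a Parzen
mixture (kernel density with a weak uniform prior), and candidates sampled
from the good mixture are ranked by the density ratio l(x)/g(x).  A plain
seeded random sampler is also provided; both are fully reproducible.

Trials whose objective raises are recorded with a score of -inf and the
search continues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Categorical", "Float", "Int",
    "RandomSampler", "TPESampler", "make_sampler",
    "Trial", "tune",
]


# ---------------------------------------------------------------------------
# search-space dimensions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __post_init__(self):
        object.__setattr__(self, "choices", tuple(self.choices))
        if not self.choices:
            raise ValueError("Categorical needs at least one choice")


@dataclass(frozen=True)
class Float:
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("Float requires low < high")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled Float requires low > 0")

    def to_unit(self, x: float) -> float:
        if self.log:
            return (math.log(x) - math.log(self.low)) / (math.log(self.high) - math.log(self.low))
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.log:
            return math.exp(math.log(self.low) + u * (math.log(self.high) - math.log(self.low)))
        return self.low + u * (self.high - self.low)


@dataclass(frozen=True)
class Int:
    low: int
    high: int  # inclusive

    def __post_init__(self):
        if not self.low <= self.high:
            raise ValueError("Int requires low <= high")

    def to_unit(self, x: int) -> float:
        if self.high == self.low:
            return 0.5
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> int:
        u = min(max(u, 0.0), 1.0)
        return int(round(self.low + u * (self.high - self.low)))


SpaceDim = Categorical | Float | Int
Space = Mapping[str, SpaceDim]


def _sample_prior(dim: SpaceDim, rng: np.random.Generator):
    if isinstance(dim, Categorical):
        return dim.choices[rng.integers(len(dim.choices))]
    if isinstance(dim, Float):
        return dim.from_unit(rng.random())
    return dim.from_unit(rng.random())


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

class RandomSampler:
    """Independent uniform sampling from the prior of each dimension."""

    def __init__(self, space: Space, seed: int | None = None):
        self.space = dict(space)
        self.rng = np.random.default_rng(seed)

    def suggest(self, history: Sequence["Trial"]) -> dict:
        return {name: _sample_prior(dim, self.rng)
                for name, dim in self.space.items()}


class TPESampler:
    """Independent per-dimension tree-structured Parzen estimator.

    Parameters follow common practice: ``n_startup`` random trials before
    the density model kicks in, the top ``gamma`` fraction of trials forms
    the "good" set, ``n_candidates`` draws from the good density compete on
    the log-density ratio.
    """

    def __init__(self, space: Space, seed: int | None = None,
                 n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24):
        self.space = dict(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def suggest(self, history: Sequence["Trial"]) -> dict:
        scored = [t for t in history if np.isfinite(t.score)]
        if len(scored) < self.n_startup:
            return {name: _sample_prior(dim, self.rng)
                    for name, dim in self.space.items()}
        scored = sorted(scored, key=lambda t: t.score, reverse=True)
        n_good = max(1, int(math.ceil(self.gamma * len(scored))))
        good = scored[:n_good]
        bad = scored[n_good:] or scored[-1:]
        params = {}
        for name, dim in self.space.items():
            gvals = [t.params[name] for t in good]
            bvals = [t.params[name] for t in bad]
            if isinstance(dim, Categorical):
                params[name] = self._suggest_categorical(dim, gvals, bvals)
            else:
                params[name] = self._suggest_numeric(dim, gvals, bvals)
        return params

    def _suggest_categorical(self, dim: Categorical, good, bad):
        def probs(vals):
            counts = np.array([sum(v == c for v in vals) for c in dim.choices],
                              dtype=float) + 1.0  # Laplace-smoothed
            return counts / counts.sum()

        pg, pb = probs(good), probs(bad)
        cand_idx = self.rng.choice(len(dim.choices), size=self.n_candidates, p=pg)
        ratios = np.log(pg[cand_idx]) - np.log(pb[cand_idx])
        return dim.choices[int(cand_idx[int(np.argmax(ratios))])]

    def _suggest_numeric(self, dim: Float | Int, good, bad):
        gu = np.array([dim.to_unit(v) for v in good])
        bu = np.array([dim.to_unit(v) for v in bad])

        def log_density(u: np.ndarray, obs: np.ndarray) -> np.ndarray:
            bw = max(1.0 / max(len(obs), 1) ** 0.5 * 0.5, 1e-3)
            # Parzen mixture of normals at the observations + uniform prior
            diffs = (u[:, None] - obs[None, :]) / bw
            kern = np.exp(-0.5 * diffs ** 2) / (bw * math.sqrt(2 * math.pi))
            dens = (kern.sum(axis=1) + 1.0) / (len(obs) + 1.0)
            return np.log(dens)

        bw_g = max(1.0 / max(len(gu), 1) ** 0.5 * 0.5, 1e-3)
        centers = gu[self.rng.integers(len(gu), size=self.n_candidates)]
        cand = np.clip(centers + self.rng.normal(0, bw_g, self.n_candidates), 0, 1)
        # a fraction of candidates from the prior keeps exploration alive
        n_prior = max(1, self.n_candidates // 4)
        cand[:n_prior] = self.rng.random(n_prior)
        ratios = log_density(cand, gu) - log_density(cand, bu)
        best = float(cand[int(np.argmax(ratios))])
        return dim.from_unit(best)


def make_sampler(space: Space, sampler: str = "tpe",
                 seed: int | None = None):
    if sampler == "tpe":
        return TPESampler(space, seed)
    if sampler == "random":
        return RandomSampler(space, seed)
    raise ValueError(f"unknown sampler {sampler!r}")


# ---------------------------------------------------------------------------
# the search loop
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    number: int
    params: dict
    score: float
    error: str | None = None


def tune(objective: Callable[[dict], float], space: Space, n_trials: int,
         sampler: str = "tpe", seed: int | None = None
         ) -> tuple[dict, list[Trial]]:
    """Maximise ``objective`` over ``space``; returns (best_params, trials).

    A trial that raises is logged with score -inf and the search continues.
    """
    if not space:
        raise ValueError("empty search space")
    sampler_obj = make_sampler(space, sampler, seed)
    trials: list[Trial] = []
    for i in range(int(n_trials)):
        params = sampler_obj.suggest(trials)
        try:
            score = float(objective(params))
            trials.append(Trial(i, params, score))
        except Exception as exc:  # noqa: BLE001 — any trial failure is non-fatal
            trials.append(Trial(i, params, float("-inf"), error=repr(exc)))
    finite = [t for t in trials if np.isfinite(t.score)]
    if not finite:
        raise RuntimeError("every hyperparameter trial failed; "
                           f"last error: {trials[-1].error}")
    best = max(finite, key=lambda t: t.score)
    return dict(best.params), trials
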