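"""Core in-memory containers.

An :class:`OmicsMatrix` is a samples x features numeric matrix in which
missing entries are first-class citizens: any non-finite value (NaN, +/-inf)
is treated as missing.  A :class:`CorrelationMatrix` holds pairwise
correlations computed under pairwise deletion; entries may be *undefined*
(insufficient overlap or zero variance on the overlap) and are stored as NaN
with an explicit ``defined`` mask — they are never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "CorrelationMatrix"]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass
class OmicsMatrix:
    """Samples x features expression matrix with explicit missing entries.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_samples, n_features)``.  Non-finite values
        are normalised to NaN and treated as missing.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        values = np.where(np.isfinite(values), values, np.nan)
        n, f = values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"f{j}" for j in range(f)]
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.feature_ids) != f:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {f} columns")
        if n < 2:
            raise ValueError("an OmicsMatrix needs at least 2 samples")
        observed = np.isfinite(values).sum(axis=1)
        if (observed == 0).any():
            bad = [self.sample_ids[i] for i in np.flatnonzero(observed == 0)]
            raise ValueError(f"samples with no observed feature: {bad}")
        self.values = values

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OmicsMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def subset(self, idx: Sequence[int]) -> "OmicsMatrix":
        idx = np.asarray(idx, dtype=int)
        return OmicsMatrix(self.values[idx],
                           [self.sample_ids[i] for i in idx],
                           list(self.feature_ids))


@dataclass
class CorrelationMatrix:
    """Pairwise correlations under pairwise deletion.

    ``entries`` is ``rows x cols``; undefined correlations are NaN and
    flagged False in :attr:`defined`.  For the square train-vs-train case the
    matrix is symmetric with unit diagonal wherever defined.
    """

    entries: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    method: str = "pearson"
    min_overlap: int = 3

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("entries shape does not match row/col ids")
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        finite = self.entries[np.isfinite(self.entries)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("defined correlations must lie in [-1, 1]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.entries)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.row_ids, columns=self.col_ids)
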