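"""Readers and writers for labelled expression matrices.

Dense matrices are CSV/TSV with sample/feature ids; sparse single-cell
counts come as MatrixMarket MTX with two plain-text sidecar files naming
rows and columns.  Default orientation follows the respective convention:
samples x features for dense tables, features x samples (genes as rows) for
MTX.  Empty cells and NA tokens map to missing; for MTX, structural zeros
optionally map to missing as well (scRNA-seq dropouts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import OmicsMatrix
from .simulate import SimulatedDataset

__all__ = ["LabeledDataset", "load_labeled_matrix", "save_dataset"]

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null", "None")


@dataclass
class LabeledDataset:
    """An expression matrix with per-sample labels and optional side tables."""

    X: OmicsMatrix
    labels: pd.Series
    covariates: pd.DataFrame | None = None
    batches: pd.Series | None = None

    def __post_init__(self) -> None:
        ids = pd.Index(self.X.sample_ids)
        labels = self.labels.reindex(ids)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise ValueError(f"labels missing for samples: {missing}")
        self.labels = labels
        if self.covariates is not None:
            extra = self.covariates.index.difference(ids).tolist()
            if extra:
                raise ValueError(f"covariate rows for unknown samples: {extra}")
        if self.batches is not None:
            extra = self.batches.index.difference(ids).tolist()
            if extra:
                raise ValueError(f"batch rows for unknown samples: {extra}")


def _read_dense(path: Path, missing_tokens) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0,
                     na_values=list(missing_tokens), keep_default_na=False,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric columns in {path.name}: {list(bad)}")
    return df


def _read_sidecar(path: Path) -> list[str]:
    names = [line.strip() for line in Path(path).read_text().splitlines()
             if line.strip()]
    if not names:
        raise ValueError(f"empty id sidecar {path}")
    return names


def _read_mtx(path: Path, zeros_as_missing: bool) -> pd.DataFrame:
    m = scipy_io.mmread(path)
    base = re.sub(r"\.mtx$", "", str(path))
    rows = _read_sidecar(Path(base + ".rows.txt"))
    cols = _read_sidecar(Path(base + ".cols.txt"))
    m = sparse.coo_matrix(m)
    if m.shape != (len(rows), len(cols)):
        raise ValueError(f"{path.name} is {m.shape} but sidecars name "
                         f"{len(rows)} rows and {len(cols)} columns")
    if zeros_as_missing:
        dense = np.full(m.shape, np.nan)
        dense[m.row, m.col] = m.data
    else:
        dense = m.toarray().astype(float)
    return pd.DataFrame(dense, index=rows, columns=cols)


def load_labeled_matrix(matrix_path, labels_path, *,
                        covariates_path=None, batches_path=None,
                        orientation: str | None = None,
                        missing_tokens=DEFAULT_MISSING_TOKENS,
                        mtx_zeros_as_missing: bool = False) -> LabeledDataset:
    """Load a matrix plus label file (and optional covariates / batch ids).

    ``orientation`` is ``samples-by-features`` or ``features-by-samples``;
    when omitted it defaults to samples-by-features for dense CSV/TSV and
    features-by-samples for MTX (the scRNA-seq genes-as-rows convention).
    """
    matrix_path = Path(matrix_path)
    is_mtx = matrix_path.suffix.lower() == ".mtx"
    if orientation is None:
        orientation = "features-by-samples" if is_mtx else "samples-by-features"
    if orientation not in ("samples-by-features", "features-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")

    df = (_read_mtx(matrix_path, mtx_zeros_as_missing) if is_mtx
          else _read_dense(matrix_path, missing_tokens))
    if orientation == "features-by-samples":
        df = df.T
    X = OmicsMatrix.from_dataframe(df)

    lab = pd.read_csv(labels_path)
    if lab.shape[1] < 2:
        raise ValueError("label file needs two columns: sample id, label")
    lab = lab.iloc[:, :2]
    lab.columns = ["sample", "label"]
    lab["sample"] = lab["sample"].astype(str)
    dup = lab["sample"][lab["sample"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample ids in label file: {dup}")
    labels = lab.set_index("sample")["label"]
    unknown = labels.index.difference(pd.Index(X.sample_ids)).tolist()
    if unknown:
        raise ValueError(f"label file names unknown samples: {unknown}")

    covariates = None
    if covariates_path is not None:
        covariates = pd.read_csv(covariates_path, index_col=0)
        covariates.index = covariates.index.astype(str)
    batches = None
    if batches_path is not None:
        b = pd.read_csv(batches_path, index_col=0)
        batches = b.iloc[:, 0]
        batches.index = batches.index.astype(str)
    return LabeledDataset(X, labels, covariates, batches)


def save_dataset(dataset: SimulatedDataset | LabeledDataset, out_dir) -> dict[str, Path]:
    """Write matrix/labels/covariate CSVs (lossless, full precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    X = dataset.X
    matrix_path = out_dir / "matrix.csv"
    X.to_dataframe().to_csv(matrix_path, float_format="%.17g")
    paths["matrix"] = matrix_path
    labels_path = out_dir / "labels.csv"
    labels = dataset.labels
    labels.rename("label").rename_axis("sample").to_csv(labels_path)
    paths["labels"] = labels_path
    cov = getattr(dataset, "covariate", None)
    if cov is None:
        cov = getattr(dataset, "covariates", None)
    if cov is not None:
        cov_path = out_dir / "covariates.csv"
        cov.rename_axis("sample").to_csv(cov_path, float_format="%.17g")
        paths["covariates"] = cov_path
    return paths
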