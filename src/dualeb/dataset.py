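"""Core dataset container and expression-matrix I/O.

Expression data live in an :class:`ExpressionDataset`: a genes x samples
matrix of log2 expression together with a binary disease label per sample
(0 = normal / wild-type, 1 = disease / knockout) and a free-text tissue tag.
Two datasets measured on the same genes and the same samples (e.g. spinal
cord and neocortex from the same animals) pair up in a
:class:`PairedDatasets`.

On-disk format is plain delimited text: genes as rows, a header of sample
ids, first column ``gene_id``; ``.csv`` means comma-separated, anything
else tab-separated. Labels are a two-column table (sample_id, label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "PairedDatasets",
    "read_expression",
    "write_expression",
    "log2_transform",
    "clean_genes",
]


def _delimiter_for(path: str | Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with per-sample binary labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    sample_ids : list of str
        Unique sample identifiers, one per matrix column.
    X : ndarray of shape (n_genes, n_samples)
        Expression values (log2 scale for all statistical operations).
    y : ndarray of shape (n_samples,)
        Binary labels, 0 = normal, 1 = disease.
    tissue : str
        Free-text tag such as ``"spinal"`` or ``"cortex"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.gene_ids) == 0:
            raise ValueError("dataset must contain at least one gene")
        if self.X.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("label vector length does not match sample count")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("labels must be 0 (normal) or 1 (disease)")
        if not np.isfinite(self.X).all():
            raise ValueError("expression matrix contains missing or non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n1(self) -> int:
        """Number of normal (label 0) samples."""
        return int(np.sum(self.y == 0))

    @property
    def n2(self) -> int:
        """Number of disease (label 1) samples."""
        return int(np.sum(self.y == 1))

    def require_class_counts(self, minimum: int = 2) -> None:
        """Raise if either class has fewer than ``minimum`` samples."""
        if self.n1 < minimum or self.n2 < minimum:
            raise ValueError(
                f"need at least {minimum} samples per class "
                f"(got n1={self.n1}, n2={self.n2})"
            )

    def subset_genes(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in index],
            X=self.X[index],
        )

    def subset_samples(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            X=self.X[:, index],
            y=self.y[index],
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.X, other.X)
        )


@dataclass
class PairedDatasets:
    """Two tissues measured on identical genes and identical samples."""

    first: ExpressionDataset
    second: ExpressionDataset

    def __post_init__(self) -> None:
        if self.first.gene_ids != self.second.gene_ids:
            raise ValueError("paired datasets must share gene ids in identical order")
        if self.first.sample_ids != self.second.sample_ids:
            raise ValueError("paired datasets must share sample ids in identical order")
        if not np.array_equal(self.first.y, self.second.y):
            raise ValueError("paired datasets must share labels")

    @property
    def gene_ids(self) -> list[str]:
        return self.first.gene_ids

    @property
    def y(self) -> np.ndarray:
        return self.first.y

    def subset_genes(self, index: np.ndarray) -> "PairedDatasets":
        return PairedDatasets(self.first.subset_genes(index), self.second.subset_genes(index))

    def subset_samples(self, index: np.ndarray) -> "PairedDatasets":
        return PairedDatasets(self.first.subset_samples(index), self.second.subset_samples(index))


def read_expression(
    path: str | Path,
    label_path: str | Path,
    tissue: str = "",
) -> ExpressionDataset:
    """Read an expression matrix and its sample labels from delimited text.

    The matrix file has genes as rows, a header row of sample ids and a
    first column of gene ids; the label file maps every sample id to 0/1.
    Gene and sample order is preserved from the file.
    """
    table = pd.read_csv(
        path, sep=_delimiter_for(path), dtype={0: str}, float_precision="round_trip"
    )
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene-id column plus at least one sample")
    gene_ids = table.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in table.columns[1:]]
    values = table.iloc[:, 1:].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = table.columns[1:][
            [not np.issubdtype(d, np.number) for d in table.iloc[:, 1:].dtypes]
        ]
        raise ValueError(f"{path}: non-numeric expression values in columns {list(bad)}")

    labels = pd.read_csv(label_path, sep=_delimiter_for(label_path), dtype={0: str})
    if labels.shape[1] < 2:
        raise ValueError(f"{label_path}: expected columns (sample_id, label)")
    label_map = dict(zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1]))
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValueError(f"samples missing from label table: {missing[:5]}")
    y = np.array([int(label_map[s]) for s in sample_ids])

    ds = ExpressionDataset(gene_ids, sample_ids, values.astype(float), y, tissue=tissue)
    ds.require_class_counts(2)
    return ds


def write_expression(dataset: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset's matrix as delimited text that ``read_expression`` inverts.

    Values are rendered with ``repr`` round-trip precision so the re-read
    matrix is bit-equal to the original.
    """
    path = Path(path)
    frame = pd.DataFrame(dataset.X, columns=dataset.sample_ids)
    frame.insert(0, "gene_id", dataset.gene_ids)
    frame.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.17g")
    return path


def write_labels(dataset: ExpressionDataset, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": dataset.sample_ids, "label": dataset.y}).to_csv(
        path, sep=_delimiter_for(path), index=False
    )
    return path


def log2_transform(raw: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Apply ``log2(x + pseudocount)`` entry-wise to a nonnegative count matrix."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if (raw.X < 0).any():
        raise ValueError("count matrix has negative entries")
    if pseudocount == 0 and (raw.X == 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    return replace(raw, X=np.log2(raw.X + pseudocount))


def clean_genes(
    dataset: ExpressionDataset,
    min_abs_lfc: float = 0.05,
    min_se: float = 1e-4,
) -> ExpressionDataset:
    """Drop genes with both a tiny class-mean difference and a tiny pooled SE.

    Genes whose absolute log2 fold change (disease minus normal class mean)
    is below ``min_abs_lfc`` *and* whose pooled standard error is below
    ``min_se`` carry no usable signal yet can produce spuriously large t
    statistics; they are removed before any ranking. Gene order is
    preserved.
    """
    if min_abs_lfc < 0 or min_se < 0:
        raise ValueError("cleaning thresholds must be nonnegative")
    dataset.require_class_counts(2)
    y = dataset.y
    n1, n2 = dataset.n1, dataset.n2
    mean0 = dataset.X[:, y == 0].mean(axis=1)
    mean1 = dataset.X[:, y == 1].mean(axis=1)
    var0 = dataset.X[:, y == 0].var(axis=1, ddof=1)
    var1 = dataset.X[:, y == 1].var(axis=1, ddof=1)
    pooled_sd = np.sqrt(((n1 - 1) * var0 + (n2 - 1) * var1) / (n1 + n2 - 2))
    se = pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    drop = (np.abs(mean1 - mean0) < min_abs_lfc) & (se < min_se)
    keep = np.flatnonzero(~drop)
    logger.info(
        "clean_genes: removed %d of %d genes (kept %d)",
        int(drop.sum()),
        dataset.n_genes,
        keep.size,
    )
    if keep.size == 0:
        raise ValueError("cleaning removed every gene; relax the thresholds")
    return dataset.subset_genes(keep)
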