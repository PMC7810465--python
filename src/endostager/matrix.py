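"""Count-matrix containers and Matrix Market / TSV round-trip I/O.

The universal input of the pipeline is an integer gene x column count table
(columns are cell barcodes for single-cell data or sample ids for bulk data),
stored dense in memory -- desk-scale problem sizes make sparsity optional --
and written to disk as Matrix Market (``matrix.mtx``) with ``genes.tsv`` and
``barcodes.tsv`` sidecars, the layout used by common droplet pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MatrixError(ValueError):
    """Raised when a count table violates its structural invariants."""


@dataclass
class GeneCountMatrix:
    """Integer gene x column count table with row/column identifiers.

    Parameters
    ----------
    values
        Non-negative integer array, shape ``(n_genes, n_columns)``.
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    column_ids
        Unique cell barcodes or sample ids, length ``n_columns``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    column_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if scipy.sparse.issparse(self.values):  # pragma: no cover - defensive
            self.values = self.values.toarray()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.column_ids = np.asarray(self.column_ids, dtype=object)
        if self.values.ndim != 2:
            raise MatrixError("count table must be two-dimensional")
        n_genes, n_cols = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.column_ids) != n_cols:
            raise MatrixError(
                f"id lengths ({len(self.gene_ids)}, {len(self.column_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise MatrixError("gene_ids are not unique")
        if len(set(self.column_ids)) != n_cols:
            raise MatrixError("column_ids are not unique")
        if self.values.size and self.values.min() < 0:
            raise MatrixError("count table contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_index(self, ids) -> np.ndarray:
        """Positions of the given column ids; unknown ids raise."""
        lookup = {c: i for i, c in enumerate(self.column_ids)}
        try:
            return np.array([lookup[c] for c in ids], dtype=int)
        except KeyError as exc:
            raise MatrixError(f"unknown column id: {exc.args[0]!r}") from exc

    def subset_columns(self, ids) -> "GeneCountMatrix":
        idx = self.column_index(ids)
        return GeneCountMatrix(self.values[:, idx], self.gene_ids, self.column_ids[idx])

    def subset_genes(self, ids) -> "GeneCountMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as exc:
            raise MatrixError(f"unknown gene id: {exc.args[0]!r}") from exc
        return GeneCountMatrix(self.values[idx, :], self.gene_ids[idx], self.column_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class PseudobulkTable:
    """Gene x group table of summed single-cell counts.

    ``n_cells_per_group`` records how many cells were pooled into each
    column; column sums equal the pooled cells' total library sizes.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    group_ids: np.ndarray
    n_cells_per_group: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.group_ids = np.asarray(self.group_ids, dtype=object)
        if self.n_cells_per_group is None:
            self.n_cells_per_group = np.ones(len(self.group_ids), dtype=int)
        self.n_cells_per_group = np.asarray(self.n_cells_per_group, dtype=int)
        if self.values.shape != (len(self.gene_ids), len(self.group_ids)):
            raise MatrixError("pseudobulk shape does not match id lists")
        if (self.n_cells_per_group <= 0).any():
            raise MatrixError("n_cells_per_group must be positive")

    def to_counts(self) -> GeneCountMatrix:
        return GeneCountMatrix(self.values, self.gene_ids, self.group_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.group_ids)


def write_mtx(counts: GeneCountMatrix, outdir: str | Path) -> None:
    """Write ``matrix.mtx`` plus ``genes.tsv`` / ``barcodes.tsv`` sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.values.astype(np.int64))
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.column_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_mtx(indir: str | Path) -> GeneCountMatrix:
    """Read a Matrix Market bundle written by :func:`write_mtx`."""
    indir = Path(indir)
    values = scipy.io.mmread(str(indir / "matrix.mtx"))
    if scipy.sparse.issparse(values):
        values = values.toarray()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    return GeneCountMatrix(np.asarray(values, dtype=np.int64), genes, barcodes)


def write_counts_tsv(counts: GeneCountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> GeneCountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return GeneCountMatrix(
        frame.to_numpy(dtype=np.int64),
        frame.index.to_numpy(dtype=object),
        frame.columns.to_numpy(dtype=object),
    )
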