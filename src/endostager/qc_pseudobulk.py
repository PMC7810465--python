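"""Cell-level QC, seeded subsampling, normalization and pseudobulk pooling.

Implements the single-cell preprocessing conventions of droplet kidney data:
cells kept when detected-gene counts fall within [200, 3000] (inclusive) and
the mitochondrial percentage is strictly below 50; log-normalization to a
10^4 scale factor; uniform subsampling of a fixed number of cells per time
point under a recorded seed (the reference workflow uses 2000 cells, seed
999); and pseudobulk pooling by exact column summation.

Random subsampling uses NumPy's PCG64 generator (``numpy.random.default_rng``);
a seed reproduces bit-exactly only within that generator family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from endostager.matrix import GeneCountMatrix, MatrixError, PseudobulkTable

logger = logging.getLogger(__name__)

MITO_PREFIX = "mt-"


def annotate_qc_covariates(
    counts: GeneCountMatrix, meta: pd.DataFrame, mito_prefix: str = MITO_PREFIX
) -> pd.DataFrame:
    """Fill in ``n_genes_detected`` / ``mito_percent`` from the matrix if absent.

    Mitochondrial genes are identified by id prefix (default ``mt-``), the
    nomenclature convention for murine mitochondrial genes.
    """
    meta = meta.copy()
    order = counts.column_index(meta["cell_id"])
    values = counts.values[:, order]
    if "n_genes_detected" not in meta.columns:
        meta["n_genes_detected"] = (values > 0).sum(axis=0)
    if "mito_percent" not in meta.columns:
        mito = np.array([str(g).startswith(mito_prefix) for g in counts.gene_ids])
        totals = values.sum(axis=0)
        meta["mito_percent"] = np.where(
            totals > 0, 100.0 * values[mito].sum(axis=0) / np.maximum(totals, 1), 0.0
        )
    return meta


def qc_filter(
    counts: GeneCountMatrix,
    meta: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 3000,
    max_mito_percent: float = 50.0,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[GeneCountMatrix, pd.DataFrame]:
    """Drop poor-quality cells and likely doublets.

    Keeps cells with ``min_genes <= n_genes_detected <= max_genes`` (bounds
    inclusive) and ``mito_percent < max_mito_percent`` (strict).  Column
    order is preserved.  Metadata must cover every column of ``counts``.
    """
    meta_cells = set(meta["cell_id"])
    for c in counts.column_ids:
        if c not in meta_cells:
            raise MatrixError(f"metadata missing for cell {c!r}")
    meta = annotate_qc_covariates(counts, meta, mito_prefix=mito_prefix)
    meta = meta.set_index("cell_id").loc[list(counts.column_ids)].reset_index()
    keep = (
        (meta["n_genes_detected"] >= min_genes)
        & (meta["n_genes_detected"] <= max_genes)
        & (meta["mito_percent"] < max_mito_percent)
    ).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("qc_filter dropped %d / %d cells", n_dropped, len(keep))
    kept_ids = counts.column_ids[keep]
    return counts.subset_columns(kept_ids), meta.loc[keep].reset_index(drop=True)


def lognormalize(counts: GeneCountMatrix, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize to ``scale`` total and apply log1p.

    entry = ln(1 + scale * count / column_sum).  Columns with zero total are
    rejected: a cell with no counts has no defined expression profile.
    """
    totals = counts.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = counts.column_ids[totals == 0][0]
        raise MatrixError(f"column {bad!r} has zero total count")
    return np.log1p(scale * counts.values / totals)


def subsample_cells(
    meta: pd.DataFrame,
    n: int = 2000,
    seed: int = 999,
    group_by: str = "timepoint_hr",
) -> dict:
    """Uniform without-replacement sample of up to ``n`` cells per group.

    Groups smaller than ``n`` are returned whole with a logged warning, so a
    shallow time point degrades the analysis gracefully rather than aborting
    it.  Deterministic for a given seed (PCG64); groups are processed in
    sorted order so the draw does not depend on row order of ``meta``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    selection: dict = {}
    groups = meta.groupby(group_by, sort=True)
    for key, frame in groups:
        # sort so the draw depends on the id set, not on metadata row order
        ids = np.sort(frame["cell_id"].to_numpy(dtype=object))
        if len(ids) == 0:
            raise MatrixError(f"group {key!r} is empty")
        if len(ids) <= n:
            if len(ids) < n:
                logger.warning(
                    "group %r has %d cells (< %d requested); keeping all", key, len(ids), n
                )
            selection[key] = list(ids)
        else:
            chosen = rng.choice(ids, size=n, replace=False)
            selection[key] = list(chosen)
    if not selection:
        raise MatrixError("no groups found to subsample")
    return selection


def pseudobulk(counts: GeneCountMatrix, selection: dict) -> PseudobulkTable:
    """Sum the selected cells' columns into one pseudobulk column per group."""
    group_ids = sorted(selection, key=str)
    cols = []
    n_cells = []
    for g in group_ids:
        idx = counts.column_index(selection[g])
        if len(idx) == 0:
            raise MatrixError(f"group {g!r} selects no cells")
        cols.append(counts.values[:, idx].sum(axis=1))
        n_cells.append(len(idx))
    values = np.stack(cols, axis=1).astype(np.int64)
    return PseudobulkTable(values, counts.gene_ids, np.array(group_ids, dtype=object), n_cells)
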