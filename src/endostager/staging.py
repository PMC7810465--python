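"""Cross-species staging of bulk query samples along the murine timeline.

The staging procedure: per-time-point one-vs-rest signatures (significant
genes with their log2 fold changes) are translated to human orthologues;
each bulk query sample gets a gene-wise log2 fold-change vector against the
mean of the reference samples; a Spearman correlation between the mouse
signature fold changes and the query fold changes -- computed per time point
over that time point's signature genes -- places each query on the timeline
at the argmax time point, summarized by coarse early/mid/late labels; and the
assigned stages are compared against clinical severity (SOFA) with a
seeded permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from endostager.matrix import GeneCountMatrix
from endostager.nb_de import (
    DEFAULT_PRIOR_COUNT,
    DEError,
    DispersionEstimate,
    NormFactors,
    estimate_dispersion,
    nb_test,
    significant_genes,
    tmm_factors,
)

logger = logging.getLogger(__name__)

#: Coarse phase of each time point (hr).  16 hr -- the transition point of
#: the endotoxemia timeline (translation shutdown, communication failure) --
#: is its own "mid" phase; this grouping is a declared convention of the
#: package, configurable in :func:`stage_queries`.
DEFAULT_STAGE_MAP: dict[int, str] = {
    0: "early",
    1: "early",
    4: "early",
    16: "mid",
    27: "late",
    36: "late",
    48: "late",
}

DEFAULT_MIN_GENES = 10


class StagingError(ValueError):
    """Raised on invalid staging inputs."""


@dataclass
class TimepointSignature:
    """FDR-significant one-vs-rest genes of a time point with log2 fold changes."""

    timepoint_hr: int
    log2fc: pd.Series  # index: gene ids

    @property
    def genes(self) -> set[str]:
        return set(self.log2fc.index)

    def __len__(self) -> int:
        return len(self.log2fc)


@dataclass
class QueryFoldChange:
    """Gene-wise log2 fold change of one query sample versus the reference mean."""

    sample_id: str
    log2fc: pd.Series
    n_reference: int


@dataclass
class StagingMatrix:
    """Query x time-point Spearman correlations with stage assignments.

    ``rho`` holds the correlation of each sample's fold-change vector with
    each time point's signature; ``assignments`` holds per sample the argmax
    stage (earliest hour on ties), its coarse label, the winning correlation
    and the gene count used.
    """

    rho: pd.DataFrame
    n_genes_used: pd.DataFrame
    assignments: pd.DataFrame


def resolve_orthologues(map_frame: pd.DataFrame) -> dict[str, str]:
    """Reduce an orthologue table to its unambiguous one-to-one pairs.

    Mouse genes with several human matches and human genes claimed by
    several mouse genes are dropped (conservative handling of one-to-many
    orthology); the dropped count is logged.
    """
    cols = list(map_frame.columns[:2])
    frame = map_frame.rename(columns={cols[0]: "mouse_gene", cols[1]: "human_gene"})
    frame = frame.drop_duplicates(["mouse_gene", "human_gene"])
    mouse_multi = frame["mouse_gene"].duplicated(keep=False)
    human_multi = frame["human_gene"].duplicated(keep=False)
    kept = frame.loc[~mouse_multi & ~human_multi]
    n_dropped = len(frame) - len(kept)
    if n_dropped:
        logger.info("dropped %d ambiguous orthologue pairs (kept %d)", n_dropped, len(kept))
    return dict(zip(kept["mouse_gene"], kept["human_gene"]))


def translate_signature(sig: TimepointSignature, mapping: dict[str, str]) -> TimepointSignature:
    """Re-key a signature from mouse to human gene ids via a resolved map.

    Unmapped genes are dropped with a logged count; fold changes carry over
    unchanged.  An empty result raises, since a time point without any
    translated gene cannot participate in staging.
    """
    translated = {mapping[g]: v for g, v in sig.log2fc.items() if g in mapping}
    n_dropped = len(sig.log2fc) - len(translated)
    if n_dropped:
        logger.info(
            "time point %s: %d signature genes had no orthologue", sig.timepoint_hr, n_dropped
        )
    if not translated:
        raise StagingError(f"no orthologues for time point {sig.timepoint_hr}")
    return TimepointSignature(sig.timepoint_hr, pd.Series(translated))


def timepoint_signatures(
    table,
    groups,
    norm: NormFactors | None = None,
    disp: DispersionEstimate | None = None,
    q: float = 0.05,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> list[TimepointSignature]:
    """One-vs-rest signature (FDR < q genes + log2 fold changes) per time point.

    Runs the NB test of each time point's columns against all others pooled;
    normalization factors and dispersions are estimated from the table when
    not supplied.  A time point with no significant gene yields an empty
    signature with a warning.
    """
    groups = np.asarray(groups)
    if norm is None:
        norm = tmm_factors(table)
    if disp is None:
        disp = estimate_dispersion(table, groups, norm)
    sigs = []
    for t in sorted(pd.unique(groups)):
        res = nb_test(table, groups, t, norm, disp, prior_count=prior_count)
        sig_rows = significant_genes(res, q=q)
        if sig_rows.empty:
            logger.warning("time point %s: no significant genes at FDR < %g", t, q)
        sigs.append(
            TimepointSignature(
                int(t), pd.Series(sig_rows["log2fc"].to_numpy(), index=sig_rows["gene_id"])
            )
        )
    return sigs


def query_foldchange(
    query: GeneCountMatrix,
    reference_ids,
    prior_cpm: float = DEFAULT_PRIOR_COUNT,
) -> list[QueryFoldChange]:
    """Per-sample log2 fold change versus the mean of the reference samples.

    Samples are library-size normalized to counts per million; each
    non-reference sample's vector is log2((cpm + prior) / (reference mean
    cpm + prior)).  At least two reference samples are required.
    """
    reference_ids = list(reference_ids)
    if len(reference_ids) < 2:
        raise StagingError("need >= 2 reference samples")
    ref_idx = set(query.column_index(reference_ids))
    totals = query.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise StagingError("sample with zero total count")
    cpm = 1e6 * query.values / totals
    ref_mean = cpm[:, sorted(ref_idx)].mean(axis=1)
    out = []
    for j, sample in enumerate(query.column_ids):
        if j in ref_idx:
            continue
        lfc = np.log2((cpm[:, j] + prior_cpm) / (ref_mean + prior_cpm))
        out.append(
            QueryFoldChange(str(sample), pd.Series(lfc, index=query.gene_ids), len(reference_ids))
        )
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Vectors must have equal length >= 3; a constant vector has no rank
    ordering, so the correlation is undefined and NaN is returned with a
    warning (callers exclude such cells from argmax decisions).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StagingError("vectors must be one-dimensional and equal-length")
    if x.size < 3:
        raise StagingError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector in spearman_rho; correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def stage_queries(
    sigs: list[TimepointSignature],
    queries: list[QueryFoldChange],
    min_genes: int = DEFAULT_MIN_GENES,
    stage_map: dict[int, str] | None = None,
) -> StagingMatrix:
    """Assign each query sample a stage by signature correlation.

    For every (sample, time point) pair, the Spearman correlation is taken
    over the intersection of the time point's translated signature genes and
    the sample's gene universe, pairing mouse and query log2 fold changes.
    Intersections below ``min_genes`` give NaN.  The assigned stage is the
    argmax time point, ties broken toward the earliest hour; coarse labels
    come from ``stage_map`` (default early = {0,1,4}, mid = {16},
    late = {27,36,48}).
    """
    nonempty = [s for s in sigs if len(s) > 0]
    if not nonempty:
        raise StagingError("no non-empty signatures to stage against")
    if not queries:
        raise StagingError("no query samples")
    stage_map = DEFAULT_STAGE_MAP if stage_map is None else stage_map
    timepoints = sorted(s.timepoint_hr for s in nonempty)
    sig_by_t = {s.timepoint_hr: s for s in nonempty}

    sample_ids = [qf.sample_id for qf in queries]
    rho = pd.DataFrame(np.nan, index=sample_ids, columns=timepoints, dtype=float)
    n_used = pd.DataFrame(0, index=sample_ids, columns=timepoints, dtype=int)
    for qf in queries:
        for t in timepoints:
            sig = sig_by_t[t]
            shared = sig.log2fc.index.intersection(qf.log2fc.index)
            n_used.loc[qf.sample_id, t] = len(shared)
            if len(shared) < max(min_genes, 3):
                logger.warning(
                    "sample %s vs %s hr: only %d shared genes (< %d); correlation skipped",
                    qf.sample_id,
                    t,
                    len(shared),
                    min_genes,
                )
                continue
            rho.loc[qf.sample_id, t] = spearman_rho(
                sig.log2fc.loc[shared].to_numpy(), qf.log2fc.loc[shared].to_numpy()
            )

    rows = []
    for sample in sample_ids:
        row = rho.loc[sample]
        if row.isna().all():
            logger.warning("sample %s: no valid correlation; left unassigned", sample)
            rows.append((sample, None, "unassigned", float("nan"), 0))
            continue
        best = row.max()
        # columns are in ascending hour order, so idxmax's first hit is the
        # earliest time point among exact ties
        assigned = int(row.idxmax())
        rows.append(
            (
                sample,
                assigned,
                stage_map.get(assigned, "unassigned"),
                float(best),
                int(n_used.loc[sample, assigned]),
            )
        )
    assignments = pd.DataFrame(
        rows, columns=["sample_id", "assigned_stage", "coarse_label", "best_rho", "n_genes_used"]
    )
    return StagingMatrix(rho, n_used, assignments)


def severity_association(
    staging: StagingMatrix,
    severity: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of assigned stage with SOFA, permutation-tested.

    Returns (rho, p) where p is the two-sided permutation p-value from
    ``n_permutations`` seeded shuffles of the severity column -- preferred
    over the large-sample approximation at biopsy-cohort sample sizes.
    """
    merged = staging.assignments.merge(severity, on="sample_id")
    merged = merged.dropna(subset=["assigned_stage", "sofa"])
    if len(merged) < 4:
        raise StagingError("need >= 4 samples with both stage and severity")
    stage_rank = stats.rankdata(merged["assigned_stage"].to_numpy(dtype=float))
    sofa_rank = stats.rankdata(merged["sofa"].to_numpy(dtype=float))
    if np.ptp(stage_rank) == 0 or np.ptp(sofa_rank) == 0:
        logger.warning("constant stage or severity; association undefined")
        return float("nan"), 1.0

    xc = stage_rank - stage_rank.mean()
    yc = sofa_rank - sofa_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rho_obs = float(xc @ yc / denom)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (n_permutations, 1)), axis=1)
    rho_perm = perms @ xc / denom
    p = (1.0 + np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12)) / (n_permutations + 1.0)
    return rho_obs, float(p)
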