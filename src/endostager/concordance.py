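"""Pseudobulk-vs-bulk concordance via directional top-k Jaccard heatmaps.

Mirrors the comparison of the single-cell time course against public bulk
kidney array data: every one-to-one condition pair gets an NB differential
expression run; each pair's gene list is sorted by FDR, split by the sign of
the log fold change, and truncated to the top k (500 in the reference
workflow); pairwise Jaccard indices between the directional lists form a
symmetric matrix whose rows are ordered by complete-linkage agglomerative
clustering on distance 1 - J.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from endostager.matrix import GeneCountMatrix, MatrixError, PseudobulkTable
from endostager.nb_de import DEError, DispersionEstimate, NormFactors, nb_test, tmm_factors

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 500


@dataclass
class DirectionalGeneLists:
    """Top-k up- and down-regulated genes of one condition comparison.

    Lists are FDR-ascending; ties broken by |log2fc| descending, then gene
    id, so the ordering is total and deterministic.  Genes with log2fc
    exactly 0 belong to neither list.
    """

    comparison_id: str
    up: list[str]
    down: list[str]
    k: int


@dataclass
class JaccardResult:
    """Symmetric comparison x comparison Jaccard matrix with linkage ordering."""

    matrix: pd.DataFrame
    linkage_order: list[str]
    merges: list[tuple[str, str, float]] = field(default_factory=list)


def pairwise_de(
    table: PseudobulkTable,
    pairs: list[tuple] | None = None,
    norm: NormFactors | None = None,
    disp: DispersionEstimate | None = None,
    fallback_dispersion: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """NB one-vs-one test for every (unordered) condition pair.

    Single pseudobulk columns carry no replication, so the test runs at the
    configured fixed dispersion unless an estimate is supplied.  Results are
    keyed by ``"<a>_vs_<b>"`` in the pair's given order.
    """
    present = set(table.group_ids)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(present, key=str), 2))
    for a, b in pairs:
        for cond in (a, b):
            if cond not in present:
                raise DEError(f"condition {cond!r} not present in table")
    if norm is None:
        norm = tmm_factors(table)
    if disp is None:
        disp = DispersionEstimate(
            fallback_dispersion, np.full(len(table.gene_ids), fallback_dispersion), 1.0
        )
    results = {}
    for a, b in pairs:
        key = f"{a}_vs_{b}"
        results[key] = nb_test(table, table.group_ids, a, norm, disp, other_group=b)
    return results


def top_k_split(
    results: pd.DataFrame, k: int = DEFAULT_TOP_K, comparison_id: str = ""
) -> DirectionalGeneLists:
    """Sort by FDR, split by fold-change sign, truncate each side to k."""
    if not np.isfinite(results["fdr"]).all():
        raise DEError("results carry non-finite FDR values")
    ordered = results.assign(_abs=results["log2fc"].abs()).sort_values(
        ["fdr", "_abs", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    up = ordered.loc[ordered["log2fc"] > 0, "gene_id"].head(k).tolist()
    down = ordered.loc[ordered["log2fc"] < 0, "gene_id"].head(k).tolist()
    return DirectionalGeneLists(comparison_id, up, down, k)


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 1 by convention (logged)."""
    a, b = set(a), set(b)
    if not a and not b:
        logger.warning("Jaccard of two empty sets; returning 1 by convention")
        return 1.0
    return len(a & b) / len(a | b)


def complete_linkage_order(
    dist: pd.DataFrame,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Leaf order and merge history of naive complete-linkage clustering.

    Distance ties are broken lexicographically on the pair of cluster
    representative labels (each cluster represented by its smallest label);
    on a merge, the cluster with the smaller representative comes first in
    the leaf order.  Naive O(n^3) is deliberate: n is tens of comparisons at
    most and the explicit algorithm doubles as documentation.
    """
    labels = [str(x) for x in dist.index]
    clusters: list[list[str]] = [[lab] for lab in labels]
    d = {(a, b): float(dist.loc[a, b]) for a in labels for b in labels}
    merges: list[tuple[str, str, float]] = []

    def cluster_dist(ca: list[str], cb: list[str]) -> float:
        return max(d[(x, y)] for x in ca for y in cb)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = cluster_dist(clusters[i], clusters[j])
                rep = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                cand = (dij, rep, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, (rep_a, rep_b), i, j = best
        first, second = (clusters[i], clusters[j])
        if min(second) < min(first):
            first, second = second, first
        merges.append((min(first), min(second), dij))
        merged = first + second
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return clusters[0], merges


def jaccard_heatmap(lists: list[DirectionalGeneLists], direction: str) -> JaccardResult:
    """Pairwise Jaccard matrix over one direction's lists, linkage-ordered."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(lists) < 2:
        raise DEError("need at least two comparisons")
    ids = [dl.comparison_id for dl in lists]
    if len(set(ids)) != len(ids):
        raise DEError("comparison ids must be unique")
    sets = {dl.comparison_id: set(getattr(dl, direction)) for dl in lists}
    matrix = pd.DataFrame(
        [[jaccard(sets[a], sets[b]) if a != b else 1.0 for b in ids] for a in ids],
        index=ids,
        columns=ids,
        dtype=float,
    )
    order, merges = complete_linkage_order(1.0 - matrix)
    ordered = matrix.loc[order, order]
    return JaccardResult(ordered, order, merges)


def harmonize_ids(counts: GeneCountMatrix, platform_map: pd.DataFrame) -> GeneCountMatrix:
    """Translate platform probe ids to gene names, discarding non-matches.

    ``platform_map`` is a two-column probe-id -> gene-name table.  Probes
    without a match are dropped (count logged); when several probes map to
    the same gene name, the row with the highest total counts survives.
    """
    if platform_map.empty:
        raise MatrixError("platform map is empty")
    cols = list(platform_map.columns[:2])
    mapping = dict(zip(platform_map[cols[0]], platform_map[cols[1]]))
    matched = [(i, mapping[g]) for i, g in enumerate(counts.gene_ids) if g in mapping]
    n_dropped = counts.n_genes - len(matched)
    if n_dropped:
        logger.info("harmonize_ids discarded %d unmatched ids", n_dropped)
    if not matched:
        raise MatrixError("no ids matched the platform map")
    totals = counts.values.sum(axis=1)
    best: dict[str, int] = {}
    for i, name in matched:
        if name not in best or totals[i] > totals[best[name]]:
            best[name] = i
    names = sorted(best)
    idx = [best[n] for n in names]
    return GeneCountMatrix(counts.values[idx, :], np.array(names, dtype=object), counts.column_ids)
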