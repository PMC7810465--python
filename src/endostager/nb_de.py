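"""Negative-binomial differential expression with TMM normalization.

A self-contained count-model engine for the two DE branches of the pipeline:
one-vs-rest contrasts across time points (cells as replicates) and one-vs-one
contrasts between single pseudobulk columns.  The components are

* trimmed mean of M-values (TMM) normalization factors: the doubly-trimmed,
  precision-weighted mean of gene-wise log ratios against a reference column,
  with factors rescaled to geometric mean 1;
* method-of-moments dispersion estimation (variance = mu + phi*mu^2) from
  within-group residuals on offset-adjusted counts, with optional shrinkage
  of per-gene estimates toward the common value;
* a per-gene Wald test on the difference of log group rates, with effective
  library sizes (library size x TMM factor) as offsets and a prior count of
  0.5 guarding log fold changes at zeros;
* Benjamini-Hochberg step-up FDR adjustment.

The engine is validated by calibration and parameter-recovery properties, not
by output-matching any particular GLM implementation; quasi-likelihood
F-tests and trended empirical-Bayes dispersions are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from endostager.matrix import GeneCountMatrix, MatrixError, PseudobulkTable

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_COUNT = 0.5
DEFAULT_FALLBACK_DISPERSION = 0.1


class DEError(ValueError):
    """Raised on invalid differential-expression inputs."""


@dataclass
class NormFactors:
    """Per-column TMM factors; geometric mean 1 by construction."""

    column_ids: np.ndarray
    factors: np.ndarray
    library_sizes: np.ndarray

    @property
    def effective_library_size(self) -> np.ndarray:
        return self.library_sizes * self.factors


@dataclass
class DispersionEstimate:
    """Common and per-gene (tagwise) NB dispersions.

    ``tagwise`` is the raw method-of-moments estimate shrunk toward
    ``common`` with weight ``shrinkage_weight`` and floored at zero.
    """

    common: float
    tagwise: np.ndarray
    shrinkage_weight: float


def _as_values(table: PseudobulkTable | GeneCountMatrix):
    if isinstance(table, PseudobulkTable):
        return table.values.astype(float), table.gene_ids, table.group_ids
    return table.values.astype(float), table.gene_ids, table.column_ids


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_logratio: float,
    trim_abundance: float,
) -> float:
    """log2 TMM factor of one column against the reference column."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        raise DEError("no genes expressed in both columns; TMM undefined")
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M; its inverse is the precision weight
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m, hi_m = np.floor(n * trim_logratio) + 1, n + 1 - (np.floor(n * trim_logratio) + 1)
    lo_a, hi_a = np.floor(n * trim_abundance) + 1, n + 1 - (np.floor(n * trim_abundance) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        raise DEError("all genes trimmed away; retry with smaller trim fractions")
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return f


def tmm_factors(
    table: PseudobulkTable | GeneCountMatrix,
    trim_logratio: float = 0.3,
    trim_abundance: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference column is the one whose upper-quartile expression fraction
    is closest to the mean upper quartile across columns.  For every other
    column, genes expressed in both are doubly trimmed (the most extreme
    ``trim_logratio`` fraction of log ratios M and ``trim_abundance``
    fraction of mean abundances A on each side are removed) and the factor is
    the precision-weighted mean of the surviving log ratios.  Factors are
    rescaled to geometric mean 1.
    """
    values, _, column_ids = _as_values(table)
    if values.shape[1] < 2:
        raise DEError("TMM needs at least two columns")
    lib = values.sum(axis=0)
    if (lib == 0).any():
        raise DEError("all-zero column; TMM undefined")
    f75 = np.quantile(values / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        if j == ref_idx:
            continue
        log_factors[j] = _tmm_pair_factor(
            values[:, j], values[:, ref_idx], lib[j], lib[ref_idx], trim_logratio, trim_abundance
        )
    factors = 2.0**log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(np.asarray(column_ids, dtype=object), factors, lib)


def estimate_dispersion(
    table: PseudobulkTable | GeneCountMatrix,
    groups,
    norm: NormFactors | None = None,
    shrinkage_weight: float = 0.5,
    fallback_dispersion: float = DEFAULT_FALLBACK_DISPERSION,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion from within-group residuals.

    For every group with >= 2 columns, each gene's group rate is estimated as
    total count over total effective library size; squared residuals around
    the fitted means, degrees-of-freedom corrected, yield per-gene dispersion
    estimates ``(sum (y-mu)^2 * n/(n-G) - sum mu) / sum mu^2``.  The common
    dispersion pools those sums over all genes.  Negative estimates are
    floored at zero after shrinkage toward the common value.

    With no replicated group at all, the configured fallback dispersion is
    returned with a warning -- the situation of single pseudobulk columns.
    """
    if not 0.0 <= shrinkage_weight <= 1.0:
        raise DEError("shrinkage_weight must be in [0, 1]")
    values, gene_ids, column_ids = _as_values(table)
    groups = np.asarray(groups)
    if groups.shape[0] != values.shape[1]:
        raise DEError("groups must align with table columns")
    eff = norm.effective_library_size if norm is not None else values.sum(axis=0)

    n_genes = values.shape[0]
    ss = np.zeros(n_genes)
    s_mu = np.zeros(n_genes)
    s_mu2 = np.zeros(n_genes)
    n_used, n_groups_used = 0, 0
    for g in pd.unique(groups):
        cols = np.flatnonzero(groups == g)
        if cols.size < 2:
            continue
        l = eff[cols]
        rate = values[:, cols].sum(axis=1) / l.sum()
        mu = rate[:, None] * l[None, :]
        ss += ((values[:, cols] - mu) ** 2).sum(axis=1)
        s_mu += mu.sum(axis=1)
        s_mu2 += (mu**2).sum(axis=1)
        n_used += cols.size
        n_groups_used += 1

    if n_groups_used == 0:
        logger.warning(
            "no group with >= 2 replicates; using fallback dispersion %.3g", fallback_dispersion
        )
        return DispersionEstimate(
            fallback_dispersion, np.full(n_genes, fallback_dispersion), 1.0
        )

    correction = n_used / (n_used - n_groups_used)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(s_mu2 > 0, (ss * correction - s_mu) / np.where(s_mu2 > 0, s_mu2, 1.0), 0.0)
    common = float(max((ss.sum() * correction - s_mu.sum()) / s_mu2.sum(), 0.0))
    tagwise = np.clip((1.0 - shrinkage_weight) * raw + shrinkage_weight * common, 0.0, None)
    return DispersionEstimate(common, tagwise, shrinkage_weight)


def _group_rate(values, eff, cols, prior_count):
    total = values[:, cols].sum(axis=1)
    l_sum = eff[cols].sum()
    l_sq = (eff[cols] ** 2).sum()
    rate = (total + prior_count) / l_sum
    return total, l_sum, l_sq, rate


def nb_test(
    table: PseudobulkTable | GeneCountMatrix,
    groups,
    target_group,
    norm: NormFactors | None = None,
    disp: DispersionEstimate | None = None,
    other_group=None,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """Per-gene NB Wald test of one group against the rest (or one other).

    Group rates are total counts over total effective library size with a
    prior count of ``prior_count`` added; the Wald statistic divides the
    difference of log rates by the delta-method standard error under the NB
    variance ``mu + phi*mu^2``.  P-values are two-sided; genes with zero
    counts everywhere are excluded from testing and reported with ``p = 1``,
    ``log2fc = 0``.  Returns a frame with columns ``gene_id``, ``log2fc``,
    ``p_value``, ``fdr``, ``mean_cpm``.
    """
    values, gene_ids, column_ids = _as_values(table)
    groups = np.asarray(groups)
    if groups.shape[0] != values.shape[1]:
        raise DEError("groups must align with table columns")
    idx1 = np.flatnonzero(groups == target_group)
    if idx1.size == 0:
        raise DEError(f"target group {target_group!r} not present")
    if other_group is not None:
        idx2 = np.flatnonzero(groups == other_group)
        if idx2.size == 0:
            raise DEError(f"comparison group {other_group!r} not present")
    else:
        idx2 = np.flatnonzero(groups != target_group)
        if idx2.size == 0:
            raise DEError("one-vs-rest contrast needs a non-empty rest")
    eff = norm.effective_library_size if norm is not None else values.sum(axis=0)
    phi = disp.tagwise if disp is not None else np.full(values.shape[0], DEFAULT_FALLBACK_DISPERSION)

    t1, l1, lsq1, r1 = _group_rate(values, eff, idx1, prior_count)
    t2, l2, lsq2, r2 = _group_rate(values, eff, idx2, prior_count)

    log2fc = np.log2(r1 / r2)
    # Var(sum y) = rate*sum(L) + phi*rate^2*sum(L^2); delta method on log rate
    v1 = (r1 * l1 + phi * r1**2 * lsq1) / (t1 + prior_count) ** 2
    v2 = (r2 * l2 + phi * r2**2 * lsq2) / (t2 + prior_count) ** 2
    z = (np.log(r1) - np.log(r2)) / np.sqrt(v1 + v2)
    p = 2.0 * stats.norm.sf(np.abs(z))

    untested = (t1 + t2) == 0
    p[untested] = 1.0
    log2fc[untested] = 0.0

    mean_cpm = 1e6 * (t1 + t2) / (l1 + l2)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": bh_adjust(p),
            "mean_cpm": mean_cpm,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(results: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Rows with ``fdr < q`` (strict), keeping the signed log2 fold change."""
    return results.loc[results["fdr"] < q, ["gene_id", "log2fc", "fdr"]].reset_index(drop=True)
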