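# Methods

## Scope

`endostager` implements a cross-species staging workflow: per-time-point
transcriptomic signatures derived from a murine single-cell endotoxemia time
course are used to place bulk human query samples on that timeline, plus a
pseudobulk-vs-bulk Jaccard concordance procedure. Upstream single-cell
machinery (clustering, integration, label transfer, pseudotime, velocity,
regulon and interaction inference, spatial anchoring) is out of scope; the
package starts from a count matrix with per-cell time-point labels.

## Synthetic data model

The generator emulates the statistical structure the staging analysis
assumes, at desk scale.

**Single-cell counts.** Gene baseline abundances are log-normal
(σ = 1.5 on the natural log), normalized to proportions. Each of the seven
time points (0, 1, 4, 16, 27, 36, 48 hr) owns a disjoint set of signature
genes (default 40) whose proportions are multiplied by `2^signature_log2fc`
(default 3) in that time point's cells, then renormalized — so the planted
effect is compositional, as real differential expression is. Per-cell
library sizes are log-normal around `mean_library_size` (default 5000
counts, σ = 0.3, enough depth variation to exercise normalization). Counts
are gamma-Poisson: variance = μ + φμ², with dispersion φ (default 0.1,
a typical single-cell value for UMI data). A small block of `mt-`-prefixed
genes receives a per-cell mitochondrial fraction drawn uniformly from
`mito_fraction_range` (default 1–10 %, i.e. healthy cells); QC covariates
(detected genes, mito %) are computed from the realized matrix. Default
group size is 300 cells per time point — large enough for stable one-vs-rest
contrasts, small enough that the full pipeline runs in seconds. The
relative per-time-point cell yields of the emulated dataset (GSE151658)
are recorded in `ENDOTOXEMIA_CELL_YIELDS` for consistency checks and
realistic group-size ratios.

**Bulk queries and references.** Queries are independent bulk libraries
(default mean depth 10⁶), not summed cells: each sample draws Poisson counts
from its true stage's expression program projected onto the human gene
universe through the orthologue map, with gene-wise multiplicative
log-normal noise of sd `noise_sd` (default study condition 0.2). Reference
samples draw from the baseline (0 hr) program. Query true stages default to
the post-baseline time points: a query generated from the 0 hr program is
statistically indistinguishable from the references, so its fold-change
vector is noise and carries no stage signal — exactly as a healthy biopsy
would be unstageable in the real procedure. The baseline state is what the
reference samples represent; `query_stages` restores 0 hr if wanted.

**Orthologue map.** A configurable fraction of genes map one-to-one
(mouse symbol → upper-cased human symbol), a fraction are absent, and the
remainder map one-to-many to exercise collision handling.

**Severity.** Integer SOFA scores:
`clamp(round(intercept + slope·stage_rank + N(0, noise_sd)), 0, 24)`,
default intercept 18 and planted slope −2 per stage rank (later stages =
recovery = milder illness), matching the direction reported for real
cohorts.

What the generator does **not** emulate: cell-type heterogeneity of the
response (all cells of a time point share one program; cell-type labels are
decorative), ambient RNA, doublets, batch effects, gene–gene correlation
beyond compositional coupling, platform differences between species, and
partially overlapping or drifting signature programs. Passing tests
therefore demonstrate correctness of the machinery and recoverability under
the stated noise model, not performance on real biopsies.

## QC, normalization, subsampling, pseudobulk

Cells are kept when detected-gene counts lie in [200, 3000] (inclusive
bounds) and mitochondrial percentage is strictly below 50. "Gene counts" is
read as detected genes per cell (the standard convention); both covariates
are recomputed from the matrix when absent from metadata, with mito genes
identified by a configurable id prefix (default `mt-`). Log-normalization is
`ln(1 + 10⁴·count/colsum)`; a zero-total column is an error.

Subsampling draws up to n cells (default 2000) per time point uniformly
without replacement using NumPy's PCG64 generator; cell ids are sorted
before drawing so the selection depends on the id set and seed, not row
order. A seed reproduces bit-exactly only within one generator family; this
package fixes PCG64. Groups smaller than n are kept whole with a warning
rather than erroring — a shallow time point should degrade the analysis, not
abort it. Pseudobulk columns are exact column sums, so total counts are
conserved.

## The NB differential-expression engine

The engine is authored here because no installed Python package provides
TMM normalization or an edgeR-style NB test; it is validated by calibration
and recovery properties rather than by output-matching any specific GLM
implementation (quasi-likelihood internals are version-dependent and out of
scope).

**TMM factors.** Reference column: upper-quartile expression fraction
closest to the column mean. Per column: genes expressed in both columns
yield log-ratios M and abundances A; the most extreme 30 % of M and 5 % of A
on each side (rank-based, mid-ranks for ties) are trimmed; the factor is the
mean of surviving M weighted by inverse delta-method variances; factors are
rescaled to geometric mean 1. The implementation agrees with edgeR's
`calcNormFactors` to ≈ 1e-5 on NB test tables (cross-checked in the suite)
and with a longhand oracle to 1e-6.

**Dispersion.** Per gene, a method-of-moments estimate from within-group
residuals: with group rates fitted as total count over total effective
library size, `φ̂ = (Σ(y−μ̂)²·n/(n−G) − Σμ̂) / Σμ̂²` over all groups with ≥ 2
columns. The common dispersion pools these sums across genes; tagwise
estimates are shrunk halfway toward it (weight 0.5) and floored at 0. With
no replicated group (single pseudobulk columns), a configured fallback
(default 0.1) is used with a warning.

**Wald test.** Group rates use a prior count of 0.5:
`r = (Σy + 0.5)/ΣL_eff`. The statistic is
`(ln r₁ − ln r₂) / sqrt(v₁ + v₂)` with
`v = (rΣL + φr²ΣL²)/(Σy + 0.5)²` (delta method under NB variance);
p-values are two-sided normal. Genes with zero counts everywhere are
excluded and reported with p = 1, log2fc = 0. Empirically the null type-I
error at 0.05 is ≈ 0.049 with 200 cells per group, sensitivity for planted
log2fc = 2 exceeds 0.95, and fold-change bias is < 0.2 — measured by the
test suite and the acceptance script.

**FDR.** Benjamini–Hochberg step-up via `statsmodels.multipletests`,
property-tested against the literal step-up definition. Significance is
strict: `fdr < q`.

For the staging branch, cells are treated as replicates within a time point
(one-vs-rest at cell level) — this makes dispersion estimable from the data.
For the concordance branch, single pseudobulk columns are compared pairwise
at the fixed fallback dispersion. Both follow from the replicate structure
each branch actually has.

## Staging

Orthologue resolution keeps only pairs unambiguous on both sides; dropping
multi-mapped pairs is the conservative default and is logged. Correlation is
computed per time point over that time point's signature genes (not the
union across time points); the per-time-point reading matches signatures
being defined per time point. Spearman's ρ is the Pearson correlation of
mid-ranks (scipy); a constant vector gives NaN with a warning and is
excluded from the argmax. Cells with fewer than `min_genes` (default 10)
shared genes are NaN — rank correlation on fewer pairs is unstable. Argmax
ties break toward the earliest hour (deterministic, and the clinically
conservative call). Coarse labels early = {0, 1, 4}, mid = {16},
late = {27, 36, 48} are a declared convention of this package: 16 hr is the
timeline's transition point (translation shutdown, cell–cell communication
failure), so it stands alone as "mid". The severity association uses a
permutation p-value (default 10,000 seeded shuffles) rather than the
large-sample approximation because cohorts can be as small as ~20 samples.

## Concordance

Pairwise NB tests for every condition pair; lists sorted by FDR with ties
broken by |log2fc| descending then gene id (a total order, needed for
determinism); split by fold-change sign; truncated to k = 500 per side.
Jaccard of two empty sets is defined as 1 with a warning (vacuous
comparisons are flagged, not fatal). Complete-linkage clustering on 1 − J is
implemented naively (O(n³); n is tens of comparisons at most) with
distance ties broken lexicographically on the pair of smallest member
labels, and the smaller-labelled cluster placed first on merge — fully
deterministic and oracle-checked. Duplicate probe collapse in
`harmonize_ids` keeps the row with the highest total counts; the rule is a
convention, as only the discarding of non-matches is prescribed upstream.

## Pipeline

`run_pipeline` executes QC → subsample → signatures → translation → query
fold changes → staging → severity association from a YAML config, writing
TSV artifacts and a JSON report. Reports carry a config fingerprint (output
location excluded — it locates results, it does not shape them) and no
timestamps, so identical inputs, config and seed reproduce every artifact
byte-for-byte. All randomness flows from the single config seed. Dropped
entities (filtered cells, unmapped genes, empty signatures, skipped
correlations) are logged at INFO/WARNING.

## Problem sizes

The standard desk-scale configuration used throughout the tests and the
acceptance script is 7 time points × 300 cells, 2000 genes, 40 signature
genes per time point at log2fc 3, dispersion 0.1, 5 reference + 54 query
bulk samples at noise sd 0.2; DE calibration runs 10 replicates of 2000
genes × 200 vs 200 cells; the severity power study uses 100 seeds × 30
samples × 10,000 permutations. The full pipeline completes in seconds on
one CPU at these sizes.

## Known limitations

- The DE engine is a transparent NB Wald engine, not a re-implementation of
  any published tool's quasi-likelihood machinery; signatures derived from
  real data may differ at the margin of the FDR threshold.
- Stage assignment is a hard argmax; no mixture or interpolation between
  time points, no uncertainty on the assignment beyond the ρ row itself.
- One-to-many orthologues are dropped, not resolved by homology confidence.
- The synthetic generator's single-program-per-time-point design makes
  staging easier than on real tissue, where cell-type composition shifts
  confound bulk fold changes; accuracy numbers on synthetic data are upper
  bounds.
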