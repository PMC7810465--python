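# endostager

Stage bulk kidney transcriptomes along a single-cell murine endotoxemia
timeline.

## The problem

Murine endotoxemia (systemic LPS exposure) is a reversible model of sepsis
whose renal response unfolds on a precise clock: injury deepens over the
first 16 hours and recovers by 48. Single-cell RNA-seq sampled at 0, 1, 4,
16, 27, 36 and 48 hr after LPS captures a transcriptomic fingerprint of each
phase. Human sepsis-associated acute kidney injury (AKI) biopsies, by
contrast, arrive with no timestamp: each patient is somewhere unknown on
their own injury/recovery trajectory. `endostager` implements the
cross-species staging idea: derive **time-point-defining gene signatures**
from the mouse time course, translate them to human orthologues, and place
each human bulk sample on the murine timeline by correlating fold-change
patterns. In the source data this partially stratifies sepsis-AKI biopsies
into early, mid and late disease, in agreement with clinical severity (SOFA
score).

The package is aimed at computational biologists who want the staging
procedure as a tested, seedable library rather than a one-off script, and at
methodologists who want to probe when it works: a first-class synthetic-data
module generates time courses with planted structure so every stage of the
pipeline can be validated against known ground truth.

## The method

1. **QC and subsampling.** Cells pass when their detected-gene count lies in
   [200, 3000] and mitochondrial percentage is < 50. From each time point,
   2000 cells (or all, if fewer) are drawn uniformly under a recorded seed.
2. **Signatures.** For each time point *t*, a one-vs-rest negative-binomial
   contrast (cells of *t* against all other cells) with TMM normalization
   factors and method-of-moments dispersion yields per-gene Wald p-values;
   genes at Benjamini–Hochberg FDR < 0.05 define the signature, each with its
   log2 fold change
   `log2fc_g(t) = log2((cpm_t + c) / (cpm_rest + c))`, prior count c = 0.5.
3. **Translation.** Mouse signature genes are re-keyed to human orthologues;
   only unambiguous one-to-one pairs are kept.
4. **Query fold changes.** Each bulk query sample *s* gets
   `log2fc_g(s) = log2((cpm_s + c) / (mean reference cpm + c))` against the
   mean of ≥ 2 healthy reference samples.
5. **Staging.** For each sample and time point, Spearman's ρ is computed
   between the mouse and query fold changes over the time point's signature
   genes; the sample's stage is the argmax time point (earliest hour on
   ties), coarsened to early {0, 1, 4}, mid {16}, late {27, 36, 48}.
6. **Severity.** The association between assigned stage and SOFA score is
   tested with a seeded permutation Spearman test.

A companion module implements the pseudobulk-vs-bulk concordance procedure:
pairwise NB tests between conditions, FDR-sorted gene lists split into top-k
up/down sets, and pairwise Jaccard matrices ordered by complete-linkage
clustering on distance 1 − J.

## Worked example

```python
from endostager import *
from endostager.synthetic_data import (
    SimConfig, simulate_timecourse, simulate_query_bulk,
    make_orthologue_map, simulate_severity,
)
from endostager.qc_pseudobulk import qc_filter, subsample_cells
from endostager.staging import (
    timepoint_signatures, resolve_orthologues, translate_signature,
    query_foldchange, stage_queries, severity_association,
)

cfg = SimConfig(seed=999)                      # 7 time points x 300 cells, 2000 genes
counts, meta, truth = simulate_timecourse(cfg)
counts_qc, meta_qc = qc_filter(counts, meta)
sel = subsample_cells(meta_qc, n=2000, seed=999)
ids = [c for t in sorted(sel) for c in sel[t]]
sub = counts_qc.subset_columns(ids)
groups = meta_qc.set_index("cell_id").loc[ids, "timepoint_hr"].to_numpy()

sigs = timepoint_signatures(sub, groups)
print({s.timepoint_hr: len(s) for s in sigs})
# {0: 298, 1: 282, 4: 291, 16: 289, 27: 278, 36: 285, 48: 290}

omap = make_orthologue_map(counts.gene_ids, 0.8, 0.1, seed=1000)
translated = [translate_signature(s, resolve_orthologues(omap)) for s in sigs]
q, smeta = simulate_query_bulk(truth, 2, 5, 0.2, seed=2000, orthologue_map=omap)
refs = smeta.loc[smeta.is_reference, "sample_id"].tolist()
result = stage_queries(translated, query_foldchange(q, refs))
print(result.assignments.head(6).to_string(index=False))
#    sample_id  assigned_stage coarse_label  best_rho  n_genes_used
# query_t01_01               1        early  0.438099           228
# query_t04_01               4        early  0.405857           233
# query_t16_01              16          mid  0.430827           236
# query_t27_01              27         late  0.418265           224
# query_t36_01              36         late  0.386143           232
# query_t48_01              48         late  0.408429           228

sev = simulate_severity(truth.true_stage, slope=-2.0, noise_sd=1.0, seed=3000)
rho, p = severity_association(result, sev, seed=999)
print(f"severity association: rho={rho:.3f}, permutation p={p:.4f}")
# severity association: rho=-0.984, permutation p=0.0001
```

Each signature contains the 40 planted marker genes of its time point
(positive log2fc) plus the other time points' markers appearing
down-regulated in the one-vs-rest contrast — the expected compositional
mirror. Every query is assigned its true stage; the planted negative
severity-vs-stage trend is recovered with ρ ≈ −0.98.

The same workflow is available from the shell:

```bash
stager simulate --outdir demo --seed 999
stager run --config config.yaml
stager concordance --pseudobulk pb.tsv --outdir conc --top-k 500
```

## Documentation

See `docs/methods.md` for the generative model behind the synthetic data,
the statistical choices in the DE engine (TMM reference selection, dispersion
shrinkage, prior counts, tie-breaks), and known limitations.
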