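"""Synthetic endotoxemia time-course data with planted structure.

Generates, at desk scale, the statistical structure the staging analysis
assumes: a gamma-Poisson (negative-binomial) single-cell count matrix over a
seven-point LPS time course (0, 1, 4, 16, 27, 36, 48 hr) with disjoint
per-time-point signature gene programs, per-cell QC covariates (detected
genes, mitochondrial percentage), bulk query/reference samples drawn from the
time-point programs on an orthologue-mapped human gene universe, a
mouse-to-human orthologue map with one-to-many cases, and integer severity
(SOFA) scores with a planted monotone relationship to stage.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from endostager.matrix import GeneCountMatrix, write_mtx

#: Recovered cells per time point (hr after LPS) in the murine endotoxemia
#: time-course dataset this simulator emulates (GEO GSE151658).  Used as
#: realistic relative group sizes; the sum is the dataset's cumulative yield.
ENDOTOXEMIA_CELL_YIELDS: dict[int, int] = {
    0: 9191,
    1: 9460,
    4: 9865,
    16: 5165,
    27: 7678,
    36: 10119,
    48: 11809,
}

DEFAULT_TIMEPOINTS: tuple[int, ...] = (0, 1, 4, 16, 27, 36, 48)

#: SOFA scores are integers on 0-24.
SOFA_MIN, SOFA_MAX = 0, 24

_CELL_TYPES = (
    "PT_S1",
    "PT_S3",
    "TAL",
    "DCT",
    "CD",
    "endothelial",
    "macrophage",
    "pericyte_stromal",
)

#: Log-normal sd of per-cell library sizes (depth variation the normalization
#: step has to absorb).
LIBRARY_SIZE_LOG_SD = 0.3


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the single-cell time-course simulator.

    Attributes
    ----------
    n_genes, n_cells_per_timepoint
        Dimensions of the simulated matrix.
    timepoints
        Strictly increasing hours post-LPS; defaults to the seven-point
        endotoxemia design.
    n_signature_genes_per_timepoint
        Size of each time point's planted program; programs are disjoint.
    signature_log2fc
        Planted log2 fold change of a time point's signature genes in its own
        cells relative to all other cells (>= 0).
    nb_dispersion
        Negative-binomial dispersion phi (variance = mu + phi*mu^2); > 0.
    mean_library_size
        Mean per-cell total count; per-cell sizes are log-normal around it.
    mito_fraction_range
        Interval in [0, 1] from which each cell's expected mitochondrial
        fraction is drawn uniformly.
    seed
        Root seed; identical seeds give bit-identical output.
    """

    n_genes: int = 2000
    n_cells_per_timepoint: int = 300
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_signature_genes_per_timepoint: int = 40
    signature_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    mean_library_size: float = 5000.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_timepoint <= 0:
            raise ConfigurationError("n_genes and n_cells_per_timepoint must be positive")
        tps = tuple(self.timepoints)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigurationError("timepoints must be strictly increasing (>= 2 points)")
        if self.n_signature_genes_per_timepoint < 0:
            raise ConfigurationError("n_signature_genes_per_timepoint must be >= 0")
        if self.signature_log2fc < 0:
            raise ConfigurationError("signature_log2fc must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size must be positive")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("mito_fraction_range must be an interval in [0, 1]")
        n_mito = _n_mito_genes(self.n_genes)
        needed = len(tps) * self.n_signature_genes_per_timepoint
        if needed > self.n_genes - n_mito:
            raise ConfigurationError(
                f"{needed} disjoint signature genes requested but only "
                f"{self.n_genes - n_mito} non-mitochondrial genes available"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery checks.

    ``signature_genes`` maps each time point to its planted gene-id set;
    ``true_stage`` maps each query-sample id to the time point whose program
    generated it (filled by :func:`simulate_query_bulk`); ``severity_slope``
    records the planted severity-vs-stage slope once severities are drawn.
    The remaining fields carry the generative program so that query samples
    can be drawn from it.
    """

    signature_genes: dict[int, set[str]]
    true_stage: dict[str, int] = field(default_factory=dict)
    severity_slope: float | None = None
    gene_ids: np.ndarray = None
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    expression_programs: pd.DataFrame = None  # genes x timepoints, proportions


def _n_mito_genes(n_genes: int) -> int:
    return min(13, max(3, n_genes // 200))  # 13 protein-coding mt genes in mammals


def _gene_universe(n_genes: int) -> np.ndarray:
    n_mito = _n_mito_genes(n_genes)
    width = len(str(n_genes))
    nuclear = [f"gene{i:0{width}d}" for i in range(n_genes - n_mito)]
    mito = [f"mt-g{i}" for i in range(n_mito)]
    return np.array(nuclear + mito, dtype=object)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson sample with variance mu + dispersion * mu^2."""
    mean = np.clip(mean, 1e-12, None)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _expression_programs(config: SimConfig, gene_ids: np.ndarray, rng: np.random.Generator):
    """Per-time-point expected expression proportions and planted gene sets."""
    n_genes = config.n_genes
    n_mito = _n_mito_genes(n_genes)
    nuclear_idx = np.arange(n_genes - n_mito)
    base_weight = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)

    n_sig = config.n_signature_genes_per_timepoint
    chosen = rng.choice(nuclear_idx, size=len(config.timepoints) * n_sig, replace=False)
    signature_genes: dict[int, set[str]] = {}
    programs = np.empty((n_genes, len(config.timepoints)))
    for j, t in enumerate(config.timepoints):
        idx = chosen[j * n_sig : (j + 1) * n_sig]
        signature_genes[t] = set(gene_ids[idx])
        w = base_weight.copy()
        w[idx] *= 2.0**config.signature_log2fc
        programs[:, j] = w / w.sum()
    frame = pd.DataFrame(programs, index=gene_ids, columns=list(config.timepoints))
    return frame, signature_genes


def simulate_timecourse(config: SimConfig) -> tuple[GeneCountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the single-cell time course.

    Returns the gene x cell count matrix, per-cell metadata (``cell_id``,
    ``timepoint_hr``, ``cell_type``, ``n_genes_detected``, ``mito_percent``)
    and the planted :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_universe(config.n_genes)
    programs, signature_genes = _expression_programs(config, gene_ids, rng)

    n_mito = _n_mito_genes(config.n_genes)
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[-n_mito:] = True

    blocks, cell_ids, tp_col, celltype_col = [], [], [], []
    lo, hi = config.mito_fraction_range
    for t in config.timepoints:
        n_cells = config.n_cells_per_timepoint
        props = programs[t].to_numpy()
        # split the program into nuclear and mito components, then recombine
        # per cell at that cell's target mitochondrial fraction
        p_nuc = props * ~mito_mask
        p_nuc = p_nuc / p_nuc.sum()
        p_mito = props * mito_mask
        p_mito = p_mito / p_mito.sum()
        f_mito = rng.uniform(lo, hi, size=n_cells)
        lib = rng.lognormal(np.log(config.mean_library_size), LIBRARY_SIZE_LOG_SD, size=n_cells)
        mu = lib * ((1.0 - f_mito) * p_nuc[:, None] + f_mito * p_mito[:, None])
        blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
        cell_ids.extend(f"cell_t{t:02d}_{i:05d}" for i in range(n_cells))
        tp_col.extend([t] * n_cells)
        celltype_col.extend(rng.choice(_CELL_TYPES, size=n_cells))

    values = np.concatenate(blocks, axis=1).astype(np.int64)
    counts = GeneCountMatrix(values, gene_ids, np.array(cell_ids, dtype=object))

    totals = values.sum(axis=0)
    mito_counts = values[mito_mask].sum(axis=0)
    meta = pd.DataFrame(
        {
            "cell_id": counts.column_ids,
            "timepoint_hr": np.array(tp_col, dtype=int),
            "cell_type": np.array(celltype_col, dtype=object),
            "n_genes_detected": (values > 0).sum(axis=0),
            "mito_percent": np.where(totals > 0, 100.0 * mito_counts / np.maximum(totals, 1), 0.0),
        }
    )
    truth = GroundTruth(
        signature_genes=signature_genes,
        gene_ids=gene_ids,
        timepoints=tuple(config.timepoints),
        expression_programs=programs,
    )
    return counts, meta, truth


def make_orthologue_map(
    genes: Sequence[str],
    frac_one_to_one: float,
    frac_unmapped: float,
    seed: int,
) -> pd.DataFrame:
    """Mouse-to-human orthologue pairs with controlled ambiguity.

    A fraction ``frac_one_to_one`` of genes map to a single human symbol,
    ``frac_unmapped`` have no row at all, and the remainder map one-to-many
    (two human symbols each) to exercise collision handling downstream.
    Human symbols follow the upper-casing convention of mouse/human symbol
    pairs.
    """
    if not (0.0 <= frac_one_to_one <= 1.0 and 0.0 <= frac_unmapped <= 1.0):
        raise ConfigurationError("fractions must lie in [0, 1]")
    if frac_one_to_one + frac_unmapped > 1.0 + 1e-12:
        raise ConfigurationError("frac_one_to_one + frac_unmapped must be <= 1")
    genes = np.asarray(list(genes), dtype=object)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    n11 = int(round(frac_one_to_one * len(genes)))
    n_un = int(round(frac_unmapped * len(genes)))
    n_un = min(n_un, len(genes) - n11)
    one_to_one = genes[order[:n11]]
    multi = genes[order[n11 + n_un :]]
    rows = [(m, str(m).upper()) for m in one_to_one]
    for m in multi:
        rows.append((m, str(m).upper()))
        rows.append((m, str(m).upper() + "-ALT"))
    frame = pd.DataFrame(rows, columns=["mouse_gene", "human_gene"])
    return frame.sort_values(["mouse_gene", "human_gene"], ignore_index=True)


def simulate_query_bulk(
    truth: GroundTruth,
    n_queries_per_stage: int,
    n_references: int,
    noise_sd: float,
    seed: int,
    orthologue_map: pd.DataFrame | None = None,
    mean_library_size: float = 1e6,
    query_stages: tuple[int, ...] | None = None,
) -> tuple[GeneCountMatrix, pd.DataFrame]:
    """Bulk query and reference samples drawn from the time-point programs.

    Reference samples follow the baseline (0 hr) program; each query sample
    follows its true stage's program, projected onto the human gene universe
    through the (one-to-one resolved) orthologue map, with gene-wise
    multiplicative log-normal noise of sd ``noise_sd`` and Poisson counting
    noise.  Queries cycle through ``query_stages``, ``n_queries_per_stage``
    each; by default these are the post-baseline time points, since a query
    drawn from the baseline program is statistically indistinguishable from
    the references -- its fold-change vector carries no stage signal -- and
    the baseline state is what the reference samples themselves represent.
    ``truth.true_stage`` is filled in place.
    """
    if n_references < 2:
        raise ConfigurationError("n_references must be >= 2 (reference mean undefined otherwise)")
    if n_queries_per_stage < 0 or noise_sd < 0:
        raise ConfigurationError("n_queries_per_stage and noise_sd must be non-negative")
    if truth.expression_programs is None:
        raise ConfigurationError("truth must come from simulate_timecourse")
    if query_stages is None:
        query_stages = tuple(truth.timepoints[1:])
    elif any(t not in truth.timepoints for t in query_stages):
        raise ConfigurationError("query_stages must be simulated time points")

    programs = truth.expression_programs
    if orthologue_map is not None:
        from endostager.staging import resolve_orthologues

        mapping = resolve_orthologues(orthologue_map)
        keep = [g for g in programs.index if g in mapping]
        if not keep:
            raise ConfigurationError("orthologue map retains no simulated genes")
        programs = programs.loc[keep]
        programs = programs / programs.sum(axis=0)
        programs.index = [mapping[g] for g in keep]

    rng = np.random.default_rng(seed)
    gene_ids = programs.index.to_numpy(dtype=object)
    columns, is_ref, true_stage_col = [], [], []
    blocks = []

    base = programs[truth.timepoints[0]].to_numpy()
    for i in range(n_references):
        lib = rng.lognormal(np.log(mean_library_size), LIBRARY_SIZE_LOG_SD)
        noise = rng.lognormal(0.0, noise_sd, size=len(gene_ids)) if noise_sd > 0 else 1.0
        blocks.append(rng.poisson(lib * base * noise))
        columns.append(f"ref_{i + 1:02d}")
        is_ref.append(True)
        true_stage_col.append(np.nan)

    for r in range(n_queries_per_stage):
        for t in query_stages:
            sample_id = f"query_t{t:02d}_{r + 1:02d}"
            lib = rng.lognormal(np.log(mean_library_size), LIBRARY_SIZE_LOG_SD)
            props = programs[t].to_numpy()
            noise = rng.lognormal(0.0, noise_sd, size=len(gene_ids)) if noise_sd > 0 else 1.0
            blocks.append(rng.poisson(lib * props * noise))
            columns.append(sample_id)
            is_ref.append(False)
            true_stage_col.append(t)
            truth.true_stage[sample_id] = t

    values = np.stack(blocks, axis=1).astype(np.int64)
    counts = GeneCountMatrix(values, gene_ids, np.array(columns, dtype=object))
    meta = pd.DataFrame(
        {"sample_id": columns, "is_reference": is_ref, "true_stage": true_stage_col}
    )
    return counts, meta


def simulate_severity(
    assignments: Mapping[str, int | float],
    slope: float,
    noise_sd: float,
    seed: int,
    intercept: float = 18.0,
) -> pd.DataFrame:
    """Integer SOFA-range severities with a planted linear trend in stage rank.

    severity = clamp(round(intercept + slope * stage_rank + noise), 0, 24)
    where stage_rank is the 0-based rank of the sample's stage among the
    distinct stages present.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    samples = list(assignments.keys())
    stages = np.array([assignments[s] for s in samples], dtype=float)
    rank_of = {t: r for r, t in enumerate(sorted(set(stages)))}
    ranks = np.array([rank_of[t] for t in stages], dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
    sofa = np.clip(np.round(intercept + slope * ranks + noise), SOFA_MIN, SOFA_MAX).astype(int)
    return pd.DataFrame({"sample_id": samples, "sofa": sofa})


def write_bundle(
    outdir: str | Path,
    counts: GeneCountMatrix,
    cell_meta: pd.DataFrame,
    truth: GroundTruth,
    query_counts: GeneCountMatrix | None = None,
    sample_meta: pd.DataFrame | None = None,
    orthologue_map: pd.DataFrame | None = None,
    severity: pd.DataFrame | None = None,
) -> None:
    """Write a simulated dataset as MTX + TSV files under ``outdir``."""
    outdir = Path(outdir)
    write_mtx(counts, outdir / "sc_counts")
    cell_meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    manifest = pd.DataFrame(
        [
            (t, g)
            for t in sorted(truth.signature_genes)
            for g in sorted(truth.signature_genes[t])
        ],
        columns=["timepoint_hr", "gene_id"],
    )
    manifest.to_csv(outdir / "ground_truth_signatures.tsv", sep="\t", index=False)
    if truth.true_stage:
        pd.DataFrame(
            sorted(truth.true_stage.items()), columns=["sample_id", "true_stage"]
        ).to_csv(outdir / "ground_truth_stages.tsv", sep="\t", index=False)
    if query_counts is not None:
        query_counts.to_frame().to_csv(outdir / "query_counts.tsv", sep="\t", index_label="gene_id")
    if sample_meta is not None:
        sample_meta.to_csv(outdir / "sample_metadata.tsv", sep="\t", index=False)
    if orthologue_map is not None:
        orthologue_map.to_csv(outdir / "orthologues.tsv", sep="\t", index=False)
    if severity is not None:
        severity.to_csv(outdir / "severity.tsv", sep="\t", index=False)
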