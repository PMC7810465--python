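"""End-to-end orchestration: QC -> subsample -> signatures -> staging -> report.

The pipeline reads a dataset bundle (MTX single-cell counts + metadata TSV,
bulk query TSV, reference-sample list, orthologue map, optional severity
table), runs the staging workflow under a single seed, writes every artifact
as TSV and a machine-readable JSON run report.  Reports contain no
timestamps, so identical inputs, config and seed reproduce them
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from endostager.matrix import GeneCountMatrix, read_counts_tsv, read_mtx
from endostager.nb_de import DEFAULT_FALLBACK_DISPERSION
from endostager.qc_pseudobulk import pseudobulk, qc_filter, subsample_cells
from endostager.staging import (
    DEFAULT_MIN_GENES,
    DEFAULT_STAGE_MAP,
    query_foldchange,
    resolve_orthologues,
    severity_association,
    stage_queries,
    timepoint_signatures,
    translate_signature,
)

logger = logging.getLogger(__name__)

EXPECTED_TIMEPOINTS = {0, 1, 4, 16, 27, 36, 48}


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run; loadable from YAML."""

    counts_dir: str
    cell_metadata: str
    query_counts: str
    references: str | list[str]
    orthologues: str
    severity: str | None = None
    outdir: str = "stager_out"
    min_genes: int = 200
    max_genes: int = 3000
    max_mito_percent: float = 50.0
    n_subsample: int = 2000
    seed: int = 999
    fdr_threshold: float = 0.05
    top_k: int = 500
    min_genes_for_rho: int = DEFAULT_MIN_GENES
    fallback_dispersion: float = DEFAULT_FALLBACK_DISPERSION
    stage_map: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MAP))
    n_permutations: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "stage_map" in raw:
            cfg.stage_map = {int(k): v for k, v in raw["stage_map"].items()}
        return cfg

    def fingerprint(self) -> str:
        # outdir is excluded: it locates the results, it does not shape them
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _reference_ids(references: str | list[str]) -> list[str]:
    if isinstance(references, (list, tuple)):
        return list(references)
    with open(references) as fh:
        return [line.strip() for line in fh if line.strip()]


def validate_inputs(config: RunConfig) -> list[str]:
    """Check the bundle for runnability; returns issues instead of raising."""
    issues: list[str] = []
    for label, path in [
        ("counts_dir", config.counts_dir),
        ("cell_metadata", config.cell_metadata),
        ("query_counts", config.query_counts),
        ("orthologues", config.orthologues),
    ]:
        if not Path(path).exists():
            issues.append(f"{label}: path not found: {path}")
    if isinstance(config.references, str) and not Path(config.references).exists():
        issues.append(f"references: path not found: {config.references}")
    if config.severity is not None and not Path(config.severity).exists():
        issues.append(f"severity: path not found: {config.severity}")
    if issues:
        return issues

    counts = read_mtx(config.counts_dir)
    meta = pd.read_csv(config.cell_metadata, sep="\t")
    for col in ("cell_id", "timepoint_hr"):
        if col not in meta.columns:
            issues.append(f"cell metadata lacks required column {col!r}")
    if "cell_id" in meta.columns:
        missing = set(counts.column_ids) - set(meta["cell_id"])
        for cell in sorted(missing)[:5]:
            issues.append(f"metadata missing for barcode {cell!r}")
    if "timepoint_hr" in meta.columns:
        alien = set(meta["timepoint_hr"]) - EXPECTED_TIMEPOINTS
        if alien:
            issues.append(
                f"unexpected time points {sorted(alien)}; expected subset of "
                f"{sorted(EXPECTED_TIMEPOINTS)}"
            )
    refs = _reference_ids(config.references)
    if len(refs) < 2:
        issues.append(f"{len(refs)} reference sample(s); staging requires >= 2")
    query = read_counts_tsv(config.query_counts)
    for r in refs:
        if r not in set(query.column_ids):
            issues.append(f"reference sample {r!r} absent from query table")
    omap = pd.read_csv(config.orthologues, sep="\t")
    if omap.shape[1] < 2:
        issues.append("orthologue map must have two columns (mouse_gene, human_gene)")
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full staging workflow; returns the run report dict.

    Stages: QC filter -> seeded per-time-point subsampling -> one-vs-rest NB
    signatures on the selected cells -> orthologue translation -> query
    fold changes vs reference mean -> Spearman staging -> severity
    association (when a severity table is provided).  All artifacts land
    under ``config.outdir``.
    """
    for label, path in [
        ("counts_dir", config.counts_dir),
        ("cell_metadata", config.cell_metadata),
        ("query_counts", config.query_counts),
        ("orthologues", config.orthologues),
    ]:
        if not Path(path).exists():
            raise FileNotFoundError(f"{label}: {path}")

    counts = read_mtx(config.counts_dir)
    meta = pd.read_csv(config.cell_metadata, sep="\t")
    query = read_counts_tsv(config.query_counts)
    refs = _reference_ids(config.references)
    omap = pd.read_csv(config.orthologues, sep="\t")
    severity = pd.read_csv(config.severity, sep="\t") if config.severity else None

    from endostager import __version__ as _version

    report: dict = {
        "software": {"package": "endostager", "version": _version},
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
        "stages": {},
    }

    counts_qc, meta_qc = qc_filter(
        counts,
        meta,
        min_genes=config.min_genes,
        max_genes=config.max_genes,
        max_mito_percent=config.max_mito_percent,
    )
    report["stages"]["qc"] = {
        "cells_in": counts.n_columns,
        "cells_kept": counts_qc.n_columns,
        "genes": counts_qc.n_genes,
    }

    selection = subsample_cells(meta_qc, n=config.n_subsample, seed=config.seed)
    selected_ids = [c for t in sorted(selection) for c in selection[t]]
    sub = counts_qc.subset_columns(selected_ids)
    sub_groups = (
        meta_qc.set_index("cell_id").loc[selected_ids, "timepoint_hr"].to_numpy()
    )
    report["stages"]["subsample"] = {
        str(t): len(selection[t]) for t in sorted(selection)
    }

    sigs = timepoint_signatures(sub, sub_groups, q=config.fdr_threshold)
    report["stages"]["signatures"] = {str(s.timepoint_hr): len(s) for s in sigs}

    mapping = resolve_orthologues(omap)
    translated = [translate_signature(s, mapping) for s in sigs if len(s) > 0]
    report["stages"]["translated_signatures"] = {
        str(s.timepoint_hr): len(s) for s in translated
    }

    qfcs = query_foldchange(query, refs)
    staging = stage_queries(
        translated, qfcs, min_genes=config.min_genes_for_rho, stage_map=config.stage_map
    )
    report["stages"]["staging"] = {
        row.sample_id: {
            "assigned_stage": None if row.assigned_stage is None else int(row.assigned_stage),
            "coarse_label": row.coarse_label,
            "best_rho": None if np.isnan(row.best_rho) else round(float(row.best_rho), 6),
            "n_genes_used": int(row.n_genes_used),
        }
        for row in staging.assignments.itertuples(index=False)
    }

    if severity is not None:
        rho, p = severity_association(
            staging, severity, n_permutations=config.n_permutations, seed=config.seed
        )
        report["severity_association"] = {
            "spearman_rho": None if np.isnan(rho) else round(float(rho), 6),
            "permutation_p": round(float(p), 6),
            "n_permutations": config.n_permutations,
        }

    _write_artifacts(config, sigs, translated, staging, report)
    return report


def _write_artifacts(config, sigs, translated, staging, report) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig_dir = outdir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for s in sigs:
        frame = pd.DataFrame({"gene_id": s.log2fc.index, "log2fc": s.log2fc.to_numpy()})
        frame.to_csv(sig_dir / f"signature_t{s.timepoint_hr:02d}.tsv", sep="\t", index=False)
    for s in translated:
        frame = pd.DataFrame({"gene_id": s.log2fc.index, "log2fc": s.log2fc.to_numpy()})
        frame.to_csv(
            sig_dir / f"signature_t{s.timepoint_hr:02d}_human.tsv", sep="\t", index=False
        )
    staging.rho.to_csv(outdir / "staging_rho.tsv", sep="\t", index_label="sample_id")
    staging.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    long = staging.rho.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="timepoint_hr", value_name="rho"
    )
    long.to_csv(outdir / "staging_rho_long.tsv", sep="\t", index=False)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
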