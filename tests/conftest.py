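import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

logging.getLogger("endostager").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def standard_run():
    """Standard synthetic time course taken through signatures + translation.

    Seven time points x 300 cells, 2000 genes, 40 signature genes per time
    point at log2fc = 3, NB dispersion 0.1, seed 999 -- the package's
    reference desk-scale configuration.
    """
    from endostager.qc_pseudobulk import qc_filter, subsample_cells
    from endostager.staging import (
        resolve_orthologues,
        timepoint_signatures,
        translate_signature,
    )
    from endostager.synthetic_data import SimConfig, make_orthologue_map, simulate_timecourse

    cfg = SimConfig(seed=999)
    counts, meta, truth = simulate_timecourse(cfg)
    counts_qc, meta_qc = qc_filter(counts, meta)
    selection = subsample_cells(meta_qc, n=2000, seed=999)
    ids = [c for t in sorted(selection) for c in selection[t]]
    sub = counts_qc.subset_columns(ids)
    groups = meta_qc.set_index("cell_id").loc[ids, "timepoint_hr"].to_numpy()
    sigs = timepoint_signatures(sub, groups)
    omap = make_orthologue_map(counts.gene_ids, frac_one_to_one=0.8, frac_unmapped=0.1, seed=1000)
    translated = [translate_signature(s, resolve_orthologues(omap)) for s in sigs]
    return {
        "config": cfg,
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "sub": sub,
        "groups": groups,
        "signatures": sigs,
        "orthologues": omap,
        "translated": translated,
    }


def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw used by the DE simulations in several test modules."""
    if dispersion == 0:
        return rng.poisson(mean)
    return rng.poisson(rng.gamma(1.0 / dispersion, mean * dispersion))
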