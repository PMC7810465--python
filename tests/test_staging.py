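"""Orthologue translation, fold-change vectors, Spearman staging, severity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from endostager.matrix import GeneCountMatrix
from endostager.staging import (
    StagingError,
    TimepointSignature,
    QueryFoldChange,
    query_foldchange,
    resolve_orthologues,
    severity_association,
    spearman_rho,
    stage_queries,
    translate_signature,
)
from endostager.synthetic_data import simulate_query_bulk, simulate_severity
from oracles import spearman as spearman_oracle


def _sig(t, mapping):
    return TimepointSignature(t, pd.Series(mapping))


class TestOrthologues:
    def test_one_to_many_pairs_dropped(self):
        frame = pd.DataFrame(
            {
                "mouse_gene": ["a", "b", "b", "c", "d"],
                "human_gene": ["A", "B1", "B2", "C", "C"],
            }
        )
        mapping = resolve_orthologues(frame)
        assert mapping == {"a": "A"}  # b ambiguous mouse-side, c/d human-side

    def test_bijective_map_preserves_genes(self):
        sig = _sig(16, {"a": 1.0, "b": -2.0})
        out = translate_signature(sig, {"a": "A", "b": "B"})
        assert out.genes == {"A", "B"}
        assert out.log2fc["A"] == 1.0 and out.log2fc["B"] == -2.0

    def test_partial_map_halves_signature(self):
        sig = _sig(4, {f"g{i}": float(i) for i in range(10)})
        mapping = {f"g{i}": f"G{i}" for i in range(5)}
        out = translate_signature(sig, mapping)
        assert len(out) == 5

    def test_empty_map_raises(self):
        with pytest.raises(StagingError, match="no orthologues for time point 27"):
            translate_signature(_sig(27, {"a": 1.0}), {})


class TestQueryFoldChange:
    def _query(self, values, ids):
        return GeneCountMatrix(
            np.asarray(values), [f"g{i}" for i in range(len(values))], ids
        )

    def test_query_equal_to_references_is_zero(self):
        col = np.array([1000, 2000, 4000])
        q = self._query(np.stack([col, col, col], axis=1), ["r1", "r2", "q"])
        (qfc,) = query_foldchange(q, ["r1", "r2"])
        assert np.allclose(qfc.log2fc.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_gene_shows_unit_lfc(self):
        ref = np.array([100000, 100000, 200000])
        qcol = np.array([200000, 100000, 200000])  # first gene doubled
        q = self._query(np.stack([ref, ref, qcol], axis=1), ["r1", "r2", "q"])
        (qfc,) = query_foldchange(q, ["r1", "r2"])
        lfc = qfc.log2fc.to_numpy()
        # library-size renormalization spreads the doubling; gap stays ~1
        assert lfc[0] - lfc[1] == pytest.approx(1.0, abs=0.01)

    def test_fewer_than_two_references_rejected(self):
        q = self._query(np.ones((3, 2), dtype=int), ["r1", "q"])
        with pytest.raises(StagingError):
            query_foldchange(q, ["r1"])

    def test_library_scale_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(100, size=(50, 4)) + 1
        q1 = self._query(values, ["r1", "r2", "q1", "q2"])
        q2 = self._query(values * 7, ["r1", "r2", "q1", "q2"])
        out1 = query_foldchange(q1, ["r1", "r2"])
        out2 = query_foldchange(q2, ["r1", "r2"])
        for a, b in zip(out1, out2):
            assert np.allclose(a.log2fc.to_numpy(), b.log2fc.to_numpy(), atol=1e-9)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_worked_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 summing to 2
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_is_nan(self):
        assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_matches_bruteforce_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(3, 30)
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(spearman_oracle(list(x), list(y)), abs=1e-9)

    @given(
        st.lists(st.integers(-100, 100), min_size=5, max_size=20, unique=True),
        st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_monotone_transform_invariance(self, x, scale):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        x = np.asarray(x, dtype=float)
        transformed = np.exp(scale * x / 50.0)  # strictly increasing, no ties
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(transformed, y), abs=1e-12)


class TestStageQueries:
    def _signatures(self):
        rng = np.random.default_rng(1)
        sigs = []
        for t in (1, 16, 48):
            genes = [f"G{t}_{i}" for i in range(30)]
            sigs.append(TimepointSignature(t, pd.Series(rng.normal(size=30), index=genes)))
        return sigs

    def test_noiseless_query_assigned_its_stage(self):
        sigs = self._signatures()
        universe = pd.concat([s.log2fc for s in sigs])
        for t, sig in zip((1, 16, 48), sigs):
            qf = QueryFoldChange(f"q{t}", universe.copy(), 2)
            # make the query match signature t and anti-match the others
            for other in sigs:
                scale = 1.0 if other.timepoint_hr == t else -1.0
                qf.log2fc.loc[other.log2fc.index] = scale * other.log2fc
            result = stage_queries(sigs, [qf])
            assert result.assignments.loc[0, "assigned_stage"] == t

    def test_tie_breaks_to_earliest_hour(self):
        sigs = self._signatures()
        # a query correlating identically with every signature: copy each
        qf = QueryFoldChange("tie", pd.concat([s.log2fc for s in sigs]), 2)
        result = stage_queries(sigs, [qf])
        row = result.rho.loc["tie"]
        assert np.allclose(row.to_numpy(), 1.0)
        assert result.assignments.loc[0, "assigned_stage"] == 1

    def test_coarse_labels(self):
        sigs = self._signatures()
        qf = QueryFoldChange("q", sigs[1].log2fc.copy(), 2)
        result = stage_queries(sigs, [qf])
        assert result.assignments.loc[0, "coarse_label"] == "mid"

    def test_small_intersection_gives_nan(self):
        sigs = self._signatures()
        qf = QueryFoldChange("tiny", sigs[0].log2fc.iloc[:4].copy(), 2)
        result = stage_queries(sigs, [qf], min_genes=10)
        assert result.assignments.loc[0, "coarse_label"] == "unassigned"
        assert result.rho.loc["tiny"].isna().all()

    def test_empty_signatures_rejected(self):
        empty = [TimepointSignature(1, pd.Series(dtype=float))]
        qf = QueryFoldChange("q", pd.Series({"a": 1.0}), 2)
        with pytest.raises(StagingError):
            stage_queries(empty, [qf])


class TestEndToEndRecovery:
    def test_stage_recovery_noisy_and_noiseless(self, standard_run):
        truth = standard_run["truth"]
        translated = standard_run["translated"]
        omap = standard_run["orthologues"]
        for noise_sd, seed in ((0.2, 2000), (0.0, 3000)):
            truth.true_stage.clear()
            q, smeta = simulate_query_bulk(
                truth, 9, 5, noise_sd, seed=seed, orthologue_map=omap
            )
            refs = smeta.loc[smeta["is_reference"], "sample_id"].tolist()
            result = stage_queries(translated, query_foldchange(q, refs))
            correct = [
                truth.true_stage[r.sample_id] == r.assigned_stage
                for r in result.assignments.itertuples(index=False)
            ]
            assert len(correct) >= 50
            assert np.mean(correct) >= (1.0 if noise_sd == 0 else 0.9)

    def test_accuracy_degrades_monotonically_with_noise(self, standard_run):
        truth = standard_run["truth"]
        translated = standard_run["translated"]
        omap = standard_run["orthologues"]
        accs = []
        for noise_sd in (0.0, 0.5, 2.0):
            truth.true_stage.clear()
            q, smeta = simulate_query_bulk(
                truth, 4, 5, noise_sd, seed=77, orthologue_map=omap
            )
            refs = smeta.loc[smeta["is_reference"], "sample_id"].tolist()
            result = stage_queries(translated, query_foldchange(q, refs))
            accs.append(
                np.mean(
                    [
                        truth.true_stage[r.sample_id] == r.assigned_stage
                        for r in result.assignments.itertuples(index=False)
                    ]
                )
            )
        assert accs[0] >= accs[-1]


class TestSeverityAssociation:
    def _staging_with_stages(self, stages):
        assignments = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(stages))],
                "assigned_stage": stages,
                "coarse_label": ["early"] * len(stages),
                "best_rho": [0.5] * len(stages),
                "n_genes_used": [30] * len(stages),
            }
        )
        from endostager.staging import StagingMatrix

        return StagingMatrix(pd.DataFrame(), pd.DataFrame(), assignments)

    def test_perfect_negative_trend(self):
        stages = [1, 4, 16, 27, 36, 48]
        staging = self._staging_with_stages(stages)
        severity = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)], "sofa": [20, 16, 12, 8, 4, 2]}
        )
        rho, p = severity_association(staging, severity, seed=1)
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_null_association_not_significant_on_average(self):
        rng = np.random.default_rng(2)
        stages = [1, 4, 16, 27, 36, 48] * 4
        staging = self._staging_with_stages(stages)
        p_values = []
        for seed in range(40):
            severity = pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(len(stages))],
                    "sofa": rng.integers(0, 25, size=len(stages)),
                }
            )
            _, p = severity_association(staging, severity, n_permutations=2000, seed=seed)
            p_values.append(p)
        assert (np.array(p_values) < 0.05).mean() <= 0.15

    def test_planted_slope_detected_in_most_seeds(self):
        stages = [1, 4, 16, 27, 36, 48] * 5  # 30 samples
        staging = self._staging_with_stages(stages)
        assignments = dict(zip(staging.assignments["sample_id"], stages))
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            severity = simulate_severity(assignments, slope=-2.0, noise_sd=1.0, seed=seed)
            rho, p = severity_association(
                staging, severity, n_permutations=2000, seed=seed + 10_000
            )
            hits += (rho < 0) and (p < 0.05)
        assert hits >= 0.9 * n_seeds

    def test_insufficient_overlap_rejected(self):
        staging = self._staging_with_stages([1, 4])
        severity = pd.DataFrame({"sample_id": ["s0", "s1"], "sofa": [5, 6]})
        with pytest.raises(StagingError):
            severity_association(staging, severity)
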