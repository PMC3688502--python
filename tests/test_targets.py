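"""Percent-rank target identification: ranking, testability, collapsing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miriscip import (
    TargetEnrichment,
    call_enriched,
    collapse_probes,
    gene_pvalue,
    merge_platform,
    percent_rank,
)
from miriscip.targets import testable_entities as reliable_in_n_replicates
from miriscip.simulate import SimulationConfig, gen_microarray


class TestTestableEntities:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, True, False, False), True),
            ((True, False, False, False), False),
            ((False, False, False, False), False),
            ((True, True, True, True), True),
        ],
    )
    def test_two_reliable_replicates_required(self, flags, expected):
        frame = pd.DataFrame([flags], index=["e1"])
        out = reliable_in_n_replicates(frame, min_reliable=2)
        assert ("e1" in out) is expected

    def test_threshold_is_configurable(self):
        frame = pd.DataFrame([[True, False, False]], index=["e1"])
        assert "e1" in reliable_in_n_replicates(frame, min_reliable=1)


class TestPercentRank:
    def test_simple_ranks(self):
        out = percent_rank([3, 1, 2])
        assert np.allclose(out, [5 / 6, 1 / 6, 0.5])

    def test_ties_get_average_ranks(self):
        out = percent_rank([2, 2, 1])
        assert np.allclose(out, [2 / 3, 2 / 3, 1 / 6])

    def test_mean_is_exactly_half(self):
        rng = np.random.default_rng(0)
        out = percent_rank(rng.lognormal(0, 1, 501))
        assert abs(out.mean() - 0.5) < 1e-12

    def test_no_ties_gives_exact_grid(self):
        rng = np.random.default_rng(1)
        n = 37
        out = np.sort(percent_rank(rng.permutation(np.arange(1, n + 1))))
        assert np.allclose(out, (np.arange(1, n + 1) - 0.5) / n)

    def test_values_strictly_inside_unit_interval(self):
        out = percent_rank([1, 10, 100])
        assert (out > 0).all() and (out < 1).all()

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -2.0], [1.0, np.inf]])
    def test_invalid_inputs_are_errors(self, bad):
        with pytest.raises(ValueError):
            percent_rank(bad)


class TestGenePvalue:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.background = rng.uniform(0, 1, 4000)

    def test_flat_entity_is_not_enriched(self):
        p = gene_pvalue([0.5, 0.5, 0.5, 0.5], self.background)
        assert p >= 0.4

    def test_high_ranks_are_significant(self):
        p = gene_pvalue([0.99, 0.98, 0.99, 0.97], self.background)
        assert p < 0.001

    def test_matches_scipy_welch_one_tailed(self):
        entity = [0.9, 0.7, 0.85, 0.8]
        expected = stats.ttest_ind(
            entity, self.background, equal_var=False, alternative="greater"
        ).pvalue
        assert gene_pvalue(entity, self.background) == pytest.approx(expected)

    def test_low_ranks_have_p_near_one(self):
        p = gene_pvalue([0.1, 0.1, 0.1, 0.1], self.background)
        assert p > 0.99

    def test_nan_replicates_ignored(self):
        p_full = gene_pvalue([0.9, 0.8, np.nan, 0.85], self.background)
        p_drop = gene_pvalue([0.9, 0.8, 0.85], self.background)
        assert p_full == pytest.approx(p_drop)

    def test_single_value_is_error(self):
        with pytest.raises(ValueError):
            gene_pvalue([0.9, np.nan, np.nan], self.background)


def _probe_records():
    return pd.DataFrame(
        {
            "transcript": ["t1", "t1", "t2", "t3"],
            "gene": ["g1", "g1", "g1", "g2"],
            "r1": [0.5, 0.9, 0.6, 0.3],
            "r2": [0.55, 0.92, 0.6, 0.35],
            "mean_rank": [0.525, 0.91, 0.6, 0.325],
            "p": [0.5, 0.01, 0.2, 0.8],
        },
        index=["p1", "p2", "p3", "p4"],
    )


class TestCollapseProbes:
    def test_minimum_p_probe_wins(self):
        out = collapse_probes(_probe_records())
        assert out.loc["g1", "chosen_probe"] == "p2"
        assert out.loc["g1", "p"] == 0.01

    def test_single_probe_gene_passes_through(self):
        out = collapse_probes(_probe_records())
        assert out.loc["g2", "chosen_probe"] == "p4"
        assert out.loc["g2", "mean_rank"] == pytest.approx(0.325)

    def test_ranks_unaltered_by_collapsing(self):
        out = collapse_probes(_probe_records())
        assert out.loc["g1", "r1"] == 0.9  # probe p2's own rank, untouched

    def test_p_tie_broken_by_larger_mean_rank_then_probe_id(self):
        df = pd.DataFrame(
            {
                "transcript": ["t1", "t1", "t1"],
                "gene": ["g", "g", "g"],
                "mean_rank": [0.7, 0.9, 0.9],
                "p": [0.05, 0.05, 0.05],
            },
            index=["pa", "pc", "pb"],
        )
        out = collapse_probes(df)
        # enumeration: p ties across all three; 0.9 > 0.7; 'pb' < 'pc'
        assert out.loc["g", "chosen_probe"] == "pb"

    def test_idempotent(self):
        once = collapse_probes(_probe_records())
        twice = collapse_probes(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMergePlatform:
    def test_fifth_rank_recomputes_p(self):
        rng = np.random.default_rng(3)
        background = rng.uniform(0, 1, 200)
        r4 = [0.95, 0.96, 0.94, 0.95]
        genes = pd.DataFrame(
            {
                "r1": [r4[0], 0.5], "r2": [r4[1], 0.5],
                "r3": [r4[2], 0.5], "r4": [r4[3], 0.5],
                "mean_rank": [np.mean(r4), 0.5],
                "p": [gene_pvalue(r4, background),
                      gene_pvalue([0.5] * 4, background)],
            },
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        extra = pd.Series([0.99], index=["g1"])
        out = merge_platform(genes, extra, background,
                             ["r1", "r2", "r3", "r4"], "r5")
        expected = gene_pvalue(r4 + [0.99], background)
        assert out.loc["g1", "p"] == pytest.approx(expected)
        assert out.loc["g1", "mean_rank"] == pytest.approx(np.mean(r4 + [0.99]))
        # the untouched gene keeps its four-replicate p
        assert out.loc["g2", "p"] == genes.loc["g2", "p"]

    def test_gene_missing_in_second_platform_keeps_p(self):
        rng = np.random.default_rng(4)
        background = rng.uniform(0, 1, 500)
        genes = pd.DataFrame(
            {"r1": [0.6], "r2": [0.7], "mean_rank": [0.65], "p": [0.123]},
            index=pd.Index(["g2"], name="gene"),
        )
        out = merge_platform(genes, pd.Series(dtype=float), background,
                             ["r1", "r2"], "r3")
        assert out.loc["g2", "p"] == 0.123

    def test_orphan_second_platform_gene_dropped(self):
        background = np.random.default_rng(5).uniform(0, 1, 500)
        genes = pd.DataFrame(
            {"r1": [0.6], "r2": [0.7], "mean_rank": [0.65], "p": [0.1]},
            index=pd.Index(["g1"], name="gene"),
        )
        extra = pd.Series([0.9], index=["g_new"])
        out = merge_platform(genes, extra, background, ["r1", "r2"], "r3")
        assert list(out.index) == ["g1"]


class TestCallEnriched:
    def test_strict_inequality_at_boundary(self):
        records = pd.DataFrame(
            {"p": [0.0009, 0.001, 0.5]}, index=["a", "b", "c"]
        )
        hits = call_enriched(records, alpha=0.001)
        assert hits.members == frozenset({"a"})

    def test_empty_records_give_empty_set(self):
        assert len(call_enriched(pd.DataFrame(columns=["p"]))) == 0


class TestTargetEnrichmentModel:
    def test_full_dropout_leaves_no_testable_genes(self):
        cfg = SimulationConfig(seed=0, n_genes=50, detect_dropout=1.0)
        table, _ = gen_microarray(cfg)
        res = TargetEnrichment(table).fit()
        assert res.n_testable_genes == 0

    def test_recovers_planted_targets(self):
        cfg = SimulationConfig(seed=11, n_genes=800, effect_log2=1.5)
        table, truth = gen_microarray(cfg)
        res = TargetEnrichment(table).fit(alpha=0.001)
        hits = res.enriched_genes.members
        recall = len(hits & truth.target_genes) / len(truth.target_genes)
        assert recall > 0.8

    def test_null_mean_rank_near_half(self):
        cfg = SimulationConfig(seed=12, n_genes=2000, frac_target_genes=0.0)
        table, _ = gen_microarray(cfg)
        res = TargetEnrichment(table).fit()
        assert 0.45 < res.mean_rank < 0.55

    def test_merged_genes_carry_five_rank_columns(self):
        cfg = SimulationConfig(seed=13, n_genes=200)
        table, _ = gen_microarray(cfg)
        res = TargetEnrichment(table).fit()
        rank_cols = [c for c in res.genes.columns if c.startswith("r")]
        assert len(rank_cols) == 5
        # nearly every gene has a fifth-platform value (dropout aside)
        assert res.genes["r5"].notna().mean() > 0.8
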