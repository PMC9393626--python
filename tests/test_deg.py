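"""DEG classification, merging, and the count-based exact test."""

import math

import numpy as np
import pandas as pd
import pytest

from wsyrnet.deg import classify_degs, count_test, merge_deg_sets
from wsyrnet.errors import ParameterError, ParseError
from wsyrnet.synthetic import gen_count_matrix


def stat_row(gene="g", log2fc=0.0, pvalue=0.5, herb="Gusuibu"):
    return {"gene": gene, "log2fc": log2fc, "pvalue": pvalue, "herb": herb}


class TestClassify:
    def test_reference_per_herb_totals(self, deg_table):
        calls = classify_degs(deg_table)
        summary = {
            herb: (
                len(sub),
                int((sub["direction"] == "up").sum()),
                int((sub["direction"] == "down").sum()),
            )
            for herb, sub in calls.groupby("herb")
        }
        assert summary == {
            "Gusuibu": (22, 19, 3),
            "Roucongrong": (26, 15, 11),
            "Yinyanghuo": (54, 30, 24),
        }

    def test_every_reference_row_called_with_sign_matching_direction(self, deg_table):
        calls = classify_degs(deg_table)
        assert len(calls) == len(deg_table)  # the table lists only DEGs
        assert ((calls["direction"] == "up") == (calls["log2fc"] > 0)).all()

    def test_null_effect_uncalled(self):
        calls = classify_degs(pd.DataFrame([stat_row(log2fc=0.0, pvalue=1e-6)]))
        assert len(calls) == 0

    def test_boundary_fold_change_uncalled(self):
        calls = classify_degs(
            pd.DataFrame([stat_row(log2fc=math.log2(1.5), pvalue=0.01)])
        )
        assert len(calls) == 0

    def test_boundary_p_uncalled(self):
        calls = classify_degs(pd.DataFrame([stat_row(log2fc=1.0, pvalue=0.05)]))
        assert len(calls) == 0

    def test_threshold_monotone_widening_never_removes_calls(self, deg_table):
        narrow = classify_degs(deg_table, fc_up=2.0, fc_down=0.5, p_max=0.01)
        wide = classify_degs(deg_table, fc_up=1.2, fc_down=0.8, p_max=0.1)
        narrow_keys = set(zip(narrow["gene"], narrow["herb"]))
        wide_keys = set(zip(wide["gene"], wide["herb"]))
        assert narrow_keys <= wide_keys

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            classify_degs(pd.DataFrame([stat_row()]), fc_up=0.9)

    def test_non_finite_stats_name_the_row(self):
        frame = pd.DataFrame([stat_row(), stat_row(gene="bad", log2fc=np.inf)])
        with pytest.raises(ParseError, match="bad"):
            classify_degs(frame)


class TestMerge:
    def test_reference_union_is_92_with_multi_herb_provenance(self, deg_table):
        merged = merge_deg_sets(classify_degs(deg_table))
        assert len(merged.genes) == 92
        multi = {g for g, prov in merged.provenance.items() if len(prov) >= 2}
        assert multi == {
            "EREG", "VCAN", "ARNT", "F5", "FOXO4", "HMOX1", "CYP4V2", "MMP7",
        }

    def test_single_herb_merge_is_identity(self, deg_table):
        gus = deg_table[deg_table["herb"] == "Gusuibu"]
        merged = merge_deg_sets(classify_degs(gus))
        assert merged.genes == frozenset(gus["gene"])

    def test_merge_matches_set_union(self):
        calls = pd.DataFrame(
            [
                stat_row("a", 1.0, 0.01, "Gusuibu"),
                stat_row("b", 1.0, 0.01, "Gusuibu"),
                stat_row("b", -1.0, 0.01, "Yinyanghuo"),
            ]
        )
        merged = merge_deg_sets(classify_degs(calls))
        assert merged.genes == {"a", "b"}
        assert merged.provenance["b"] == {"Gusuibu": "up", "Yinyanghuo": "down"}


class TestCountTest:
    def test_all_zero_gene_is_degenerate(self):
        counts, groups, _ = gen_count_matrix(20, 0, 0, seed=3)
        counts.iloc[0] = 0
        stats = count_test(counts, groups)
        assert stats.iloc[0]["log2fc"] == 0.0
        assert stats.iloc[0]["pvalue"] == 1.0

    def test_single_group_rejected(self):
        counts, groups, _ = gen_count_matrix(10, 0, 0, seed=1)
        with pytest.raises(ParameterError):
            count_test(counts, pd.Series("control", index=counts.columns))

    def test_non_integer_counts_rejected(self):
        counts, groups, _ = gen_count_matrix(10, 0, 0, seed=1)
        counts = counts.astype(float)
        counts.iloc[0, 0] = 1.5
        with pytest.raises(ParseError):
            count_test(counts, groups)

    def test_null_type_one_error_close_to_nominal(self):
        rates = []
        for seed in range(3):
            counts, groups, _ = gen_count_matrix(500, 0, 0, seed=seed)
            stats = count_test(counts, groups)
            rates.append((stats["pvalue"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_planted_fourfold_recovery(self):
        counts, groups, truth = gen_count_matrix(400, 40, 2.0, dispersion=0.1, seed=3)
        stats = count_test(counts, groups).assign(herb="Gusuibu")
        called = set(classify_degs(stats)["gene"])
        assert len(called & truth.deg_ids) / len(truth.deg_ids) >= 0.8

    def test_low_dispersion_screen_controls_false_discoveries(self):
        # At alpha ~ 0.01 the biological noise floor sqrt(2*alpha/n)/ln2
        # sits far below the 1.5-fold cutoff, so the FC+p rule controls
        # the false-discovery proportion; at alpha ~ 0.1 it cannot
        # (null log2FC sd ~ 0.3), which is a property of the rule, not
        # of the test statistic.
        counts, groups, truth = gen_count_matrix(400, 40, 2.0, dispersion=0.01, seed=5)
        stats = count_test(counts, groups).assign(herb="Gusuibu")
        called = set(classify_degs(stats)["gene"])
        assert len(called & truth.deg_ids) / len(truth.deg_ids) >= 0.8
        fdp = len(called - truth.deg_ids) / max(len(called), 1)
        assert fdp <= 0.1

    def test_fold_change_sign_tracks_planted_direction(self):
        counts, groups, truth = gen_count_matrix(100, 10, -2.0, seed=7)
        stats = count_test(counts, groups).set_index("gene")
        assert (stats.loc[sorted(truth.deg_ids), "log2fc"] < 0).all()
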