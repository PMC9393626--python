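"""Docking-hit screening, RMSD and the cross-receptor summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wsyrnet.docking import (
    ScreenRule,
    both_receptor_hits,
    rmsd,
    rule_from_table,
    screen_hits,
    summarize_screen,
)
from wsyrnet.errors import ParameterError, ParseError
from wsyrnet.synthetic import gen_docking_table

ESR1_EXPECTED = [
    "Marckine",
    "Xanthogalenol",
    "Arachidonate",
    "Yinyanghuo A",
    "Linoleyl acetate",
    "Suchilactone",
    "davallioside A_qt",
]
ESR2_EXPECTED = [
    "Anhydroicaritin",
    "8-Isopentenyl-kaempferol",
    "davallioside A_qt",
    "xanthogalenol",
    "Linoleyl acetate",
]


class TestReferenceScreens:
    def test_esr1_retention_list_and_order(self, docking_tables):
        rule = rule_from_table(docking_tables["ESR1"], 0.75, "ESR1")
        hits = screen_hits(docking_tables["ESR1"], rule)
        assert hits["name"].tolist() == ESR1_EXPECTED
        assert hits["score"].max() == pytest.approx(54.5303, abs=5e-4)
        assert hits["score"].min() == pytest.approx(49.7764, abs=5e-4)

    def test_esr2_retention_list_and_order(self, docking_tables):
        rule = rule_from_table(docking_tables["ESR2"], 0.90, "ESR2")
        hits = screen_hits(docking_tables["ESR2"], rule)
        assert hits["name"].tolist() == ESR2_EXPECTED
        assert hits["score"].max() == pytest.approx(50.9932, abs=5e-4)
        assert hits["score"].min() == pytest.approx(49.0539, abs=5e-4)

    def test_fraction_one_retains_nothing(self, docking_tables):
        rule = rule_from_table(docking_tables["ESR1"], 1.0, "ESR1")
        assert len(screen_hits(docking_tables["ESR1"], rule)) == 0

    def test_missing_pose_rows_never_retained(self, docking_tables):
        rule = ScreenRule(control_score=-100.0, fraction=1.0, receptor="ESR1")
        hits = screen_hits(docking_tables["ESR1"], rule)
        missing_ids = set(
            docking_tables["ESR1"].loc[
                docking_tables["ESR1"]["missing"] == 1, "mol_id"
            ]
        )
        assert not (set(hits["mol_id"]) & missing_ids)


class TestRuleValidation:
    def test_no_control_row_rejected(self, docking_tables):
        table = docking_tables["ESR1"]
        with pytest.raises(ParseError, match="control"):
            rule_from_table(table[table["is_control"] == 0], 0.75)

    def test_multiple_control_rows_rejected(self, docking_tables):
        table = docking_tables["ESR1"]
        doubled = pd.concat([table, table[table["is_control"] == 1]])
        with pytest.raises(ParseError):
            rule_from_table(doubled, 0.75)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ScreenRule(control_score=50.0, fraction=1.5)


class TestSyntheticScreens:
    @pytest.mark.parametrize("n_hits", [0, 4, 19])
    def test_planted_hit_counts(self, n_hits):
        table, truth = gen_docking_table(20, 60.0, 0.75, n_hits, seed=2, n_missing=1)
        hits = screen_hits(table, rule_from_table(table, 0.75))
        assert set(hits["mol_id"]) == set(truth.hit_ids)

    @given(
        fraction=st.floats(min_value=0.5, max_value=1.0),
        seed=st.integers(min_value=0, max_value=500),
    )
    def test_fraction_monotonicity_and_control_exclusion(self, fraction, seed):
        table, _ = gen_docking_table(15, 55.0, 0.7, 5, seed=seed)
        loose = screen_hits(table, ScreenRule(55.0, 0.5))
        tight = screen_hits(table, ScreenRule(55.0, fraction))
        assert set(tight["mol_id"]) <= set(loose["mol_id"])
        assert "CTRL" not in set(loose["mol_id"])


class TestRmsd:
    def test_identical_coordinates(self):
        coords = [(0.0, 0.0, 0.0), (1.0, 1.0, 1.0)]
        result = rmsd(coords, coords)
        assert result.rmsd_angstrom == 0.0
        assert result.reliable

    def test_single_atom_displacement_is_boundary(self):
        result = rmsd([(0, 0, 0)], [(2, 0, 0)])
        assert result.rmsd_angstrom == pytest.approx(2.0)
        assert not result.reliable  # strict < 2 A

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            rmsd([(0, 0, 0)], [(0, 0, 0), (1, 1, 1)])

    @given(st.integers(min_value=0, max_value=1000))
    def test_matches_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 10, 3))
        expected = np.sqrt(sum(np.sum((pa - pb) ** 2) for pa, pb in zip(a, b)) / 10)
        assert rmsd(a, b).rmsd_angstrom == pytest.approx(float(expected), rel=1e-12)


class TestSummary:
    def test_reference_cross_receptor_hits(self, docking_tables):
        retained = {
            r: screen_hits(
                docking_tables[r],
                rule_from_table(docking_tables[r], f, r),
            )
            for r, f in (("ESR1", 0.75), ("ESR2", 0.90))
        }
        both = both_receptor_hits(retained)
        # xanthogalenol, davallioside A_qt and linoleyl acetate pass both.
        assert both == ["MOL001645", "MOL009078", "MOL009091"]
        summary = summarize_screen(retained)
        assert set(summary.loc[summary["n_receptors"] == 2, "mol_id"]) == set(both)

    def test_single_receptor_summary_is_that_screen(self, docking_tables):
        rule = rule_from_table(docking_tables["ESR2"], 0.90, "ESR2")
        hits = screen_hits(docking_tables["ESR2"], rule)
        summary = summarize_screen({"ESR2": hits})
        assert set(summary["mol_id"]) == set(hits["mol_id"])

    def test_synthetic_summary_matches_planting(self):
        t1, truth1 = gen_docking_table(12, 50.0, 0.8, 3, seed=4)
        t2, truth2 = gen_docking_table(12, 50.0, 0.8, 5, seed=4)
        retained = {
            "A": screen_hits(t1, rule_from_table(t1, 0.8)),
            "B": screen_hits(t2, rule_from_table(t2, 0.8)),
        }
        summary = summarize_screen(retained)
        assert set(summary["mol_id"]) == set(truth1.hit_ids) | set(truth2.hit_ids)
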