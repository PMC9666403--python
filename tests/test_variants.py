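"""Substitution parsing, property-change classification, variant tables."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tubmap import (
    MutationRecord,
    MutationTable,
    PlantedEnrichmentParams,
    PropertyTable,
    classify_substitution,
    load_variant_table,
    make_variant_table,
    parse_substitution,
    tabulate,
)
from tubmap.structure import CANONICAL_AA

AA = list(CANONICAL_AA)

# hand-built property sets, written out independently of the package tables
POSITIVE = {"K", "R"}
NEGATIVE = {"D", "E"}
HYDROPHOBIC = {"A", "C", "F", "I", "L", "M", "V"}


def oracle_flags(wt, mut, h_positive=False):
    pos = POSITIVE | ({"H"} if h_positive else set())
    def charge(a):
        return "+" if a in pos else "-" if a in NEGATIVE else "0"
    flags = set()
    if charge(wt) != "0" and charge(mut) != charge(wt):
        flags.add("charge_loss_or_swap")
    if charge(wt) == "0" and charge(mut) != "0":
        flags.add("charge_gain")
    if (wt in HYDROPHOBIC) != (mut in HYDROPHOBIC):
        flags.add("hydrophobicity_change")
    return flags or {"no_change"}


class TestParse:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("R402C", ("R", 402, "C")),
            ("p.Val409Ile", ("V", 409, "I")),
            ("p.R402H", ("R", 402, "H")),
            ("Arg264Cys", ("R", 264, "C")),
        ],
    )
    def test_accepted_forms(self, text, expected):
        assert parse_substitution(text) == expected

    @pytest.mark.parametrize(
        "text", ["R402R", "p.Arg402Arg", "X402C", "A999Z", "402C", "R402", ""]
    )
    def test_rejected_forms(self, text):
        with pytest.raises(ValueError):
            parse_substitution(text)


class TestClassify:
    @pytest.mark.parametrize(
        "wt,mut,expected",
        [
            ("E", "K", {"charge_loss_or_swap"}),  # charge swap
            ("V", "I", {"no_change"}),  # both hydrophobic, both neutral
            ("R", "C", {"charge_loss_or_swap", "hydrophobicity_change"}),
            ("G", "K", {"charge_gain"}),
            ("S", "F", {"hydrophobicity_change"}),
        ],
    )
    def test_reference_substitutions(self, wt, mut, expected):
        assert classify_substitution(wt, mut) == frozenset(expected)

    def test_all_380_ordered_pairs_match_hand_oracle(self):
        for wt in AA:
            for mut in AA:
                if wt == mut:
                    continue
                assert classify_substitution(wt, mut) == frozenset(
                    oracle_flags(wt, mut)
                ), (wt, mut)

    def test_no_change_exactly_when_no_property_changes(self):
        for wt in AA:
            for mut in AA:
                if wt == mut:
                    continue
                flags = classify_substitution(wt, mut)
                if "no_change" in flags:
                    assert flags == frozenset({"no_change"})
                    assert oracle_flags(wt, mut) == {"no_change"}

    def test_histidine_toggle_only_affects_pairs_with_h(self):
        props = PropertyTable(histidine_positive=True)
        for wt in AA:
            for mut in AA:
                if wt == mut:
                    continue
                default = classify_substitution(wt, mut)
                toggled = classify_substitution(wt, mut, props)
                if "H" not in (wt, mut):
                    assert default == toggled
                assert toggled == frozenset(oracle_flags(wt, mut, h_positive=True))

    @given(
        st.sampled_from(AA), st.sampled_from(AA)
    )
    def test_flags_nonempty_and_consistent(self, wt, mut):
        if wt == mut:
            return
        flags = classify_substitution(wt, mut)
        assert flags
        assert ("no_change" in flags) == (len(flags) == 1 and "no_change" in flags)


class TestMutationRecord:
    def test_silent_substitution_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            MutationRecord("R", 402, "R", "pachygyria", frozenset({"no_change"}))

    def test_no_change_excludes_other_flags(self):
        with pytest.raises(ValueError):
            MutationRecord(
                "R", 402, "C", "pachygyria",
                frozenset({"no_change", "charge_gain"}),
            )


class TestLoadTable:
    def test_three_row_fixture(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "substitution\tphenotype\tsource\n"
            "R2C\tlissencephaly\tlit\n"
            "p.Glu5Lys\tpachygyria\tlit\n"
            "V9I\tnot available\tdb\n"
        )
        table = load_variant_table(p)
        assert table.count == 3
        assert all(r.change_flags for r in table.records)
        assert table.records[2].phenotype == "not_available"
        assert table.records[0].metadata["source"] == "lit"
        assert table.n_dropped() == 1

    def test_unknown_code_is_parse_error(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("substitution\tphenotype\nA999Z\tpachygyria\n")
        with pytest.raises(ValueError):
            load_variant_table(p)

    def test_wild_type_cross_checked_against_structure(self, toy, tmp_path):
        wt = toy.alpha_wt()
        pos = 5
        wrong = next(a for a in CANONICAL_AA if a != wt[pos])
        mut = next(a for a in CANONICAL_AA if a not in (wrong, wt[pos]))
        p = tmp_path / "v.tsv"
        p.write_text(
            f"substitution\tphenotype\n{wrong}{pos}{mut}\tpachygyria\n"
        )
        with pytest.raises(ValueError, match=f"position {pos}"):
            load_variant_table(p, model=toy.model)

    def test_synthetic_119_row_table(self, toy, tmp_path):
        params = PlantedEnrichmentParams(
            n_per_phenotype={
                "lissencephaly": 14, "microlissencephaly": 13,
                "pachygyria": 13, "polymicrogyria": 13, "not_available": 66,
            },
            seed=11,
        )
        out = tmp_path / "v119.tsv"
        make_variant_table(params, toy.alpha_labels(), toy.alpha_wt(), str(out))
        table = load_variant_table(out, model=toy.model)
        assert table.count == 119
        assert table.clinically_labeled().count == 53
        assert table.n_dropped() == 66


class TestTabulate:
    def _table(self, rows):
        recs = [
            MutationRecord(w, p, m, ph, classify_substitution(w, m))
            for w, p, m, ph in rows
        ]
        return MutationTable(recs)

    def test_degenerate_all_one_category(self):
        table = self._table(
            [("A", i, "V", "pachygyria") for i in range(1, 6)]
        )
        counts = tabulate(
            table, lambda p: "helix", categories=["helix", "sheet", "loop"]
        )
        assert counts == {"helix": 5, "sheet": 0, "loop": 0}

    def test_restrict_drops_unlabeled_and_conserves_counts(self):
        table = self._table(
            [("A", 1, "V", "pachygyria"), ("A", 2, "V", "not_available"),
             ("A", 3, "V", "lissencephaly")]
        )
        full = tabulate(table, lambda p: "helix")
        labeled = tabulate(table, lambda p: "helix", restrict="labeled")
        assert sum(full.values()) == sum(labeled.values()) + table.n_dropped()

    def test_unlabeled_position_is_hard_error(self):
        table = self._table([("A", 7, "V", "pachygyria")])
        with pytest.raises(ValueError, match="no category"):
            tabulate(table, {}.get)

    def test_planted_allocation_counted_exactly(self, toy, tmp_path):
        """tabulate through MutationTable equals raw pandas tallies."""
        labels = toy.alpha_labels()
        out = tmp_path / "v.tsv"
        make_variant_table(
            PlantedEnrichmentParams(fold=5.0, seed=3), labels,
            toy.alpha_wt(), str(out),
        )
        df = pd.read_csv(out, sep="\t")
        df["pos"] = df.substitution.str.extract(r"(\d+)").astype(int)
        df["cat"] = df.pos.map(labels)
        expected = df.cat.value_counts().to_dict()
        table = load_variant_table(out)
        got = tabulate(table, labels.get)
        assert got == expected
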