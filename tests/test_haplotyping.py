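import itertools
import random

import numpy as np
import pytest

from barcodegap.haplotyping import (
    MISSING,
    StructuralEvent,
    all_combinations,
    assignment_success,
    best_barcode,
    code_alignment,
    collapse_haplotypes,
    combination_name,
)
from barcodegap.io_formats import DataError, LocusAlignment

from _util import make_hapset, make_table, sic_oracle


def aln_from(seqs, genus="Testus", locus="locA"):
    return LocusAlignment(genus, locus, {f"s{i}": s for i, s in enumerate(seqs)})


def indel_chars(coded):
    return [(c.start, c.end) for c in coded.characters if c.kind == "indel"]


class TestIndelCoding:
    def test_single_one_bp_gap(self):
        coded = code_alignment(aln_from(["ACGT", "AC-T"]))
        assert indel_chars(coded) == [(2, 2)]
        i = [c.kind for c in coded.characters].index("indel")
        assert coded.vector("s0")[i] == "0"
        assert coded.vector("s1")[i] == "1"

    def test_invariant_gap_not_coded(self):
        coded = code_alignment(aln_from(["A--T", "A--T"]))
        assert indel_chars(coded) == []

    def test_nested_gap_scored_missing(self):
        # gaps 1-3 and 2-3 differ in boundaries: two characters; the
        # narrow one is unscorable (missing) for the wide-gap specimen
        coded = code_alignment(aln_from(["ACGGT", "A---T", "AC--T"]))
        chars = indel_chars(coded)
        assert chars == [(1, 3), (2, 3)]
        kinds = [c.kind for c in coded.characters]
        narrow = [
            i for i, c in enumerate(coded.characters)
            if c.kind == "indel" and (c.start, c.end) == (2, 3)
        ][0]
        assert coded.vector("s1")[narrow] == MISSING
        assert coded.vector("s0")[narrow] == "0"
        assert coded.vector("s2")[narrow] == "1"

    def test_matches_interval_inspection_oracle_exhaustive(self):
        # all 3-row gap-mask configurations, exhaustively up to length 5
        for length in (2, 3, 4, 5):
            for masks in itertools.combinations_with_replacement(
                range(2**length - 1), 3  # exclude the all-gap row
            ):
                rows = [
                    "".join("-" if m >> i & 1 else "A" for i in range(length))
                    for m in masks
                ]
                coded = code_alignment(aln_from(rows))
                got = {
                    (c.start, c.end): [coded.vector(f"s{i}")[k] for i in range(3)]
                    for k, c in enumerate(coded.characters)
                    if c.kind == "indel"
                }
                assert got == sic_oracle(rows), rows

    def test_structural_annotation_masks_substitutions(self):
        # inverted window 1-3 differs between the two groups
        aln = aln_from(["AAGCT", "AAGCT", "ATCGT", "ATCGT"])
        plain = code_alignment(aln)
        assert {c.kind for c in plain.characters} == {"sub"}
        assert len(plain.characters) == 3
        coded = code_alignment(aln, [StructuralEvent("inversion", 1, 3)])
        assert [c.kind for c in coded.characters] == ["struct"]
        assert coded.vector("s0")[0] != coded.vector("s2")[0]

    def test_annotation_out_of_bounds(self):
        with pytest.raises(DataError, match="bounds"):
            code_alignment(aln_from(["ACGT", "ACGA"]), [StructuralEvent("inv", 2, 4)])


class TestCollapse:
    def table3(self):
        return make_table({"spA": ["s0", "s1"], "spB": ["s2"]})

    def test_counts(self):
        coded = {"locA": code_alignment(aln_from(["AAA", "AAA", "AAT"]))}
        hs = collapse_haplotypes(coded, ["locA"], self.table3())
        assert sorted(len(h.members) for h in hs.haplotypes) == [1, 2]
        assert hs.n_sequenced == 3

    def test_dropout_changes_n_sequenced(self):
        full = aln_from(["AAA", "AAT", "ATT"], locus="trnH-psbA")
        partial = LocusAlignment("Testus", "matK", {"s0": "CCC", "s1": "CCA"})
        coded = {"trnH-psbA": code_alignment(full), "matK": code_alignment(partial)}
        t = self.table3()
        hs_one = collapse_haplotypes(coded, ["trnH-psbA"], t)
        hs_two = collapse_haplotypes(coded, ["matK", "trnH-psbA"], t)
        assert hs_one.n_sequenced == 3
        assert hs_two.n_sequenced == 2

    def test_combined_patterns_multiply(self):
        # locus X groups (s0,s1 | s2); locus Y groups (s0 | s1,s2) -> 3 classes
        coded = {
            "X": code_alignment(aln_from(["AA", "AA", "AT"], locus="X")),
            "Y": code_alignment(aln_from(["CC", "CG", "CG"], locus="Y")),
        }
        hs = collapse_haplotypes(coded, ["X", "Y"], self.table3())
        assert len(hs.haplotypes) == 3

    def test_strict_keeps_n_distinct(self):
        coded = {"L": code_alignment(aln_from(["AAT", "ANT", "AGT"], locus="L"))}
        strict = collapse_haplotypes(coded, ["L"], self.table3(), "strict")
        compat = collapse_haplotypes(coded, ["L"], self.table3(), "compatible")
        assert len(strict.haplotypes) == 3
        assert len(compat.haplotypes) == 2

    def test_member_counts_partition_n_sequenced(self):
        rng = random.Random(0)
        seqs = ["".join(rng.choice("AT") for _ in range(4)) for _ in range(12)]
        t = make_table({"sp": [f"s{i}" for i in range(12)]})
        coded = {"L": code_alignment(aln_from(seqs, locus="L"))}
        hs = collapse_haplotypes(coded, ["L"], t)
        assert sum(len(h.members) for h in hs.haplotypes) == hs.n_sequenced == 12

    def test_specimen_order_invariance(self):
        seqs = {"s0": "AAT", "s1": "AGT", "s2": "AAT"}
        t = self.table3()
        a = LocusAlignment("Testus", "L", seqs)
        b = LocusAlignment("Testus", "L", dict(reversed(list(seqs.items()))))
        ha = collapse_haplotypes({"L": code_alignment(a)}, ["L"], t)
        hb = collapse_haplotypes({"L": code_alignment(b)}, ["L"], t)
        assert {frozenset(h.members) for h in ha.haplotypes} == {
            frozenset(h.members) for h in hb.haplotypes
        }

    def test_empty_combination_rejected(self):
        with pytest.raises(DataError):
            collapse_haplotypes({}, [], self.table3())


class TestAssignment:
    def test_mixed_sharing(self):
        # species X on {A,B}, Y on {B,C}; members A:2, B:3, C:1
        hs = make_hapset(
            ["AA", "AT", "TT"],
            species=[{"X"}, {"X", "Y"}, {"Y"}],
            members=[["x1", "x2"], ["x3", "y1", "y2"], ["y3"]],
        )
        row = assignment_success(hs)
        assert row["n_private_haplotypes"] == 2
        assert row["n_individuals_identified"] == 3
        assert row["percent_identified"] == pytest.approx(50.0)

    def test_all_private(self):
        hs = make_hapset(["AA", "AT"], species=[{"X"}, {"X"}])
        assert assignment_success(hs)["percent_identified"] == 100.0

    def test_fully_shared(self):
        hs = make_hapset(["AA"], species=[{"X", "Y", "Z"}], members=[["a", "b", "c"]])
        assert assignment_success(hs)["percent_identified"] == 0.0


class TestBestBarcode:
    def row(self, name, loci, pct, n=10):
        return {
            "combination": name,
            "loci": loci,
            "n_sequenced": n,
            "percent_identified": pct,
        }

    def test_higher_percent_wins(self):
        ranking, best = best_barcode(
            [self.row("a", ["x"], 40.0), self.row("b", ["y"], 60.0)]
        )
        assert best["combination"] == "b"

    def test_tie_prefers_fewer_loci(self):
        ranking, best = best_barcode(
            [
                self.row("three", ["x", "y", "z"], 60.0),
                self.row("one", ["x"], 60.0),
            ]
        )
        assert best["combination"] == "one"

    def test_tie_prefers_larger_sample(self):
        ranking, best = best_barcode(
            [
                self.row("small", ["x"], 60.0, n=5),
                self.row("large", ["y"], 60.0, n=9),
            ]
        )
        assert best["combination"] == "large"

    def test_dropout_makes_single_locus_win(self):
        # adding a dropout-ridden locus shrinks the sample without adding
        # discrimination, so the single locus ranks first
        t = make_table({"spA": ["s0", "s1"], "spB": ["s2", "s3"]})
        good = LocusAlignment(
            "Testus", "trnH-psbA",
            {"s0": "AAAA", "s1": "AAAT", "s2": "TTTT", "s3": "TTTA"},
        )
        droppy = LocusAlignment("Testus", "matK", {"s0": "CC", "s2": "CA"})
        coded = {"trnH-psbA": code_alignment(good), "matK": code_alignment(droppy)}
        rows = [
            assignment_success(collapse_haplotypes(coded, c, t))
            for c in (("trnH-psbA",), ("matK", "trnH-psbA"))
        ]
        _, best = best_barcode(rows)
        assert best["loci"] == ["trnH-psbA"]
        assert best["n_sequenced"] == 4


def test_option_names_match_canonical_combinations():
    assert combination_name(["matK", "rpoC1"]) == "Option1"
    assert combination_name(["rpoB", "trnH-psbA"]) == "Option6"
    assert combination_name(["matK", "rpoB", "trnH-psbA"]) == "Option9"
    assert combination_name(["matK", "rpoC1", "rpoB", "trnH-psbA"]) == "Option11"
    assert combination_name(["matK"]) == "matK"
    assert combination_name(["locX", "locY"]) == "locX+locY"


def test_all_combinations_of_four_loci():
    combos = all_combinations(["matK", "rpoC1", "rpoB", "trnH-psbA"])
    assert len(combos) == 15
    assert combos[0] == ("matK",)
    assert combos[-1] == ("matK", "rpoC1", "rpoB", "trnH-psbA")
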