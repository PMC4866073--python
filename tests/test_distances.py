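import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodegap.distances import (
    barcoding_gap,
    concatenate,
    distance_matrix,
    k2p,
    write_phylip,
)
from barcodegap.io_formats import DataError, LocusAlignment

from _util import make_table


def k2p_closed_form(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identity(self):
        r = k2p("ACGT", "ACGT")
        assert r.defined and r.distance == 0.0
        assert (r.P, r.Q, r.n_sites) == (0.0, 0.0, 4)

    def test_single_transition(self):
        # one A<->G change over 4 sites: P = 1/4, d = -ln(1/2)/2
        r = k2p("ACGT", "GCGT")
        assert r.P == pytest.approx(0.25)
        assert r.Q == 0.0
        assert r.distance == pytest.approx(-0.5 * math.log(0.5), abs=1e-12)
        assert r.distance == pytest.approx(0.34657, abs=1e-5)

    def test_pairwise_deletion(self):
        r = k2p("AC-T", "ACGT")
        assert (r.n_sites, r.distance) == (3, 0.0)
        rn = k2p("ACNT", "ACGT")
        assert rn.n_sites == 3

    def test_saturation_flagged(self):
        r = k2p("AAAA", "GGGG")  # P = 1
        assert not r.defined and "saturation" in r.reason
        assert math.isnan(r.distance)

    def test_no_comparable_sites_flagged(self):
        r = k2p("--AA", "GG--")
        assert not r.defined and r.n_sites == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(DataError):
            k2p("ACG", "ACGT")

    def test_transversions_counted(self):
        r = k2p("AAAA", "ACAA")  # one A<->C transversion
        assert r.Q == pytest.approx(0.25) and r.P == 0.0
        assert r.distance == pytest.approx(k2p_closed_form(0.0, 0.25))

    @pytest.mark.parametrize("k", [1, 2, 5, 10, 20])
    def test_jukes_cantor_limit(self, k):
        # with Q = 0 and small P the distance reduces to ~P (within 5 %)
        n = 1000
        a = "A" * n
        b = "G" * k + "A" * (n - k)
        r = k2p(a, b)
        assert r.Q == 0.0
        assert abs(r.distance - r.P) / r.P < 0.05

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        pair=st.integers(2, 60).flatmap(
            lambda L: st.tuples(
                st.text(alphabet="ACGTN-", min_size=L, max_size=L),
                st.text(alphabet="ACGTN-", min_size=L, max_size=L),
            )
        )
    )
    def test_symmetry_and_range_property(self, pair):
        a, b = pair
        r_ab, r_ba = k2p(a, b), k2p(b, a)
        assert r_ab.n_sites == r_ba.n_sites <= len(a)
        assert r_ab.defined == r_ba.defined
        if r_ab.defined:
            assert r_ab.distance == pytest.approx(r_ba.distance)
            assert r_ab.distance >= 0.0

    def test_monotone_in_p_at_fixed_q(self):
        for Q in (0.0, 0.05, 0.1):
            ds = [
                k2p_closed_form(P, Q)
                for P in np.linspace(0.0, (1 - Q) / 2 - 0.01, 30)
            ]
            assert all(b > a for a, b in zip(ds, ds[1:]))


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = LocusAlignment("G", "L", {f"s{i}": "ACGTACGT" for i in range(3)})
        dm = distance_matrix(aln)
        assert np.allclose(dm.d, 0.0)
        assert dm.defined.all()

    def test_pair_value_matches_k2p(self):
        aln = LocusAlignment("G", "L", {"a": "ACGT", "b": "GCGT"})
        dm = distance_matrix(aln)
        assert dm.get("a", "b") == pytest.approx(-0.5 * math.log(0.5))

    def test_label_permutation_consistency(self):
        rng = random.Random(0)
        base = [rng.choice("ACGT") for _ in range(60)]
        rows = {}
        for i in range(5):
            seq = list(base)
            for pos in rng.sample(range(60), 5):
                seq[pos] = rng.choice("ACGT")
            rows[f"s{i}"] = "".join(seq)
        dm1 = distance_matrix(LocusAlignment("G", "L", rows))
        rows2 = dict(reversed(list(rows.items())))
        dm2 = distance_matrix(LocusAlignment("G", "L", rows2))
        for a in rows:
            for b in rows:
                if a != b:
                    assert dm1.get(a, b) == pytest.approx(dm2.get(a, b))

    def test_undefined_entries_propagate(self):
        aln = LocusAlignment("G", "L", {"a": "AAAA", "b": "GGGG", "c": "AAAA"})
        dm = distance_matrix(aln)
        assert dm.has_undefined()
        assert ("a", "b") in dm.undefined_pairs()

    def test_concatenation_restricts_to_complete_specimens(self):
        alns = {
            "X": LocusAlignment("G", "X", {"a": "AA", "b": "AT", "c": "AA"}),
            "Y": LocusAlignment("G", "Y", {"a": "CC", "b": "CC"}),
        }
        cat = concatenate(alns, ["X", "Y"])
        assert sorted(cat.rows) == ["a", "b"]
        assert cat.rows["a"] == "AACC"

    def test_phylip_export(self, tmp_path):
        aln = LocusAlignment("G", "L", {"a": "ACGT", "b": "GCGT"})
        p = tmp_path / "m.phy"
        write_phylip(distance_matrix(aln), p)
        lines = p.read_text().splitlines()
        assert lines[0] == "2" and len(lines) == 3


class TestBarcodingGap:
    def test_separable_species_have_gap(self):
        t = make_table({"X": ["x1", "x2"], "Y": ["y1", "y2"]}, genus="G")
        seq_x, seq_y = "A" * 50, "A" * 40 + "G" * 5 + "C" * 5
        aln = LocusAlignment("G", "L", {"x1": seq_x, "x2": seq_x,
                                        "y1": seq_y, "y2": seq_y})
        gap = barcoding_gap(distance_matrix(aln), t)
        for s in gap.per_species:
            assert s.max_intraspecific == 0.0
            assert s.nn_distance > 0.0
            assert s.gap_present is True

    def test_divergent_intraspecific_classes_break_gap(self):
        # species X holds two classes ~0.05 apart while its nearest
        # neighbour sits ~0.01 away: the capture signature
        base = "A" * 100
        far = "G" * 5 + "A" * 95       # 5 transitions from base
        near = "A" * 99 + "G"          # 1 transition from base
        t = make_table({"X": ["x1", "x2"], "Y": ["y1", "y2"]}, genus="G")
        aln = LocusAlignment("G", "L", {"x1": base, "x2": far,
                                        "y1": near, "y2": near})
        gap = barcoding_gap(distance_matrix(aln), t)
        x = next(s for s in gap.per_species if s.species == "X")
        assert x.max_intraspecific > x.nn_distance
        assert x.gap_present is False

    def test_singleton_species_reported_undefined(self):
        t = make_table({"X": ["x1", "x2"], "Y": ["y1"]}, genus="G")
        aln = LocusAlignment(
            "G", "L",
            {"x1": "A" * 20, "x2": "A" * 19 + "T", "y1": "A" * 16 + "G" * 4},
        )
        gap = barcoding_gap(distance_matrix(aln), t)
        y = next(s for s in gap.per_species if s.species == "Y")
        assert y.max_intraspecific is None
        assert y.nn_distance is not None
        assert y.gap_present is None

    def test_pooled_lists_and_histogram(self):
        t = make_table({"X": ["x1", "x2"], "Y": ["y1", "y2"]}, genus="G")
        seq_y = "A" * 45 + "G" * 5
        aln = LocusAlignment("G", "L", {"x1": "A" * 50, "x2": "A" * 50,
                                        "y1": seq_y, "y2": seq_y})
        gap = barcoding_gap(distance_matrix(aln), t)
        assert len(gap.intraspecific) == 2
        assert len(gap.interspecific) == 4
        hist = gap.histograms()
        assert sum(hist["interspecific"]) == 4
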