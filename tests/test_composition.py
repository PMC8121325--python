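"""Composition, skew arithmetic and aggregation, including property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import (
    GenomeSpec,
    base_composition,
    generate_genome,
    group_summary,
    region_composition,
    skew_from_fractions,
)
from mitocomp.genomes import AnnotatedGenome, reverse_complement

dna = st.text(alphabet="ACGT", min_size=4, max_size=300)


class TestBaseComposition:
    def test_symmetric_sequence_has_zero_skew(self):
        s = base_composition("AATT")
        assert s.pctA == 50 and s.pctT == 50
        assert s.at_skew == 0

    def test_counts_and_percentages(self):
        s = base_composition("AAACGT")
        assert (s.countA, s.countC, s.countG, s.countT) == (3, 1, 1, 1)
        assert s.pctA == pytest.approx(50)
        assert abs(s.pctA + s.pctC + s.pctG + s.pctT - 100) < 1e-9

    def test_n_and_gaps_excluded(self):
        assert base_composition("AANN--TT").length == 4

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="no countable"):
            base_composition("NNNN")

    def test_case_insensitive(self):
        assert base_composition("acgt").countA == base_composition("ACGT").countA

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_skew_antisymmetry_under_reverse_complement(self, s):
        if s.count("A") + s.count("T") == 0 or s.count("G") + s.count("C") == 0:
            return
        fwd = base_composition(s)
        rev = base_composition(reverse_complement(s))
        assert rev.at_skew == pytest.approx(-fwd.at_skew, abs=1e-12)
        assert rev.gc_skew == pytest.approx(-fwd.gc_skew, abs=1e-12)
        assert -1 <= fwd.at_skew <= 1 and -1 <= fwd.gc_skew <= 1

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_shuffle_invariance(self, s):
        if set(s) == set():
            return
        shuffled = "".join(np.random.default_rng(0).permutation(list(s)))
        a, b = base_composition(s), base_composition(shuffled)
        assert (a.countA, a.countC, a.countG, a.countT) == \
               (b.countA, b.countC, b.countG, b.countT)


class TestSkewFromFractions:
    def test_published_subfamily_row(self):
        at, gc = skew_from_fractions(46.36, 34.10, 8.34, 11.20)
        assert round(at, 4) == 0.1524

    def test_published_whole_genome_rows(self):
        at, gc = skew_from_fractions(42.7, 33.9, 9.9, 13.5)
        assert round(at, 3) == 0.115 and round(gc, 3) == -0.154
        at_g, _ = skew_from_fractions(43.9, 33.1, 9.7, 13.3)
        assert round(at_g, 3) == 0.140

    def test_balanced_fractions_give_zero(self):
        assert skew_from_fractions(35, 35, 15, 15) == (0, 0)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            skew_from_fractions(0, 0, 50, 50)


class TestRegionComposition:
    def test_all_regions_present_on_full_genome(self, sim_genome):
        rc = region_composition(sim_genome)
        assert set(rc) == {"Whole", "PCGs", "1st codon position", "2nd codon position",
                           "3rd codon position", "tRNA", "16S", "12S", "CR"}

    def test_codon_positions_partition_pcg_concatenation(self, sim_genome):
        rc = region_composition(sim_genome)
        total = sum(rc[f"{k} codon position"].length for k in ("1st", "2nd", "3rd"))
        assert total == rc["PCGs"].length
        # all simulated PCGs are multiples of 3 -> equal position counts
        lengths = {rc[f"{k} codon position"].length for k in ("1st", "2nd", "3rd")}
        assert len(lengths) == 1

    def test_partial_codons_keep_their_bases(self, ewen_genome):
        # frame-aware split: the two genes of length 3k+1 (cox2, nad5) each
        # put their extra base on the first codon position
        rc = region_composition(ewen_genome)
        p1 = rc["1st codon position"].length
        p2 = rc["2nd codon position"].length
        p3 = rc["3rd codon position"].length
        assert p1 + p2 + p3 == rc["PCGs"].length == 10964
        assert (p1, p2, p3) == (3656, 3654, 3654)

    def test_generator_composition_recovered(self):
        g = generate_genome(GenomeSpec(length=15000, target_at=78.0,
                                       target_at_skew=0.08, seed=1))
        rc = region_composition(g)
        assert rc["Whole"].pctAT == pytest.approx(78.0, abs=1.0)
        assert rc["Whole"].at_skew == pytest.approx(0.08, abs=0.03)

    def test_region_lengths_match_annotation(self, ewen_genome):
        rc = region_composition(ewen_genome)
        assert rc["Whole"].length == 14830
        assert rc["16S"].length == 1188
        assert rc["12S"].length == 727
        assert rc["CR"].length == 525
        assert rc["tRNA"].length == 1429
        assert rc["PCGs"].length == 10964


class TestGroupSummary:
    def _mk(self, seed, subfamily):
        g = generate_genome(GenomeSpec(length=15000, seed=seed, subfamily=subfamily))
        return g

    def test_single_member_group_equals_member(self):
        g = self._mk(1, "A")
        df = group_summary([g], "subfamily")
        s = base_composition(g.sequence)
        assert df.loc["A", "AT-skew"] == pytest.approx(s.at_skew, abs=1e-12)

    def test_mean_of_percentages_hand_oracle(self):
        # two species at A/T = 40/36 and 44/32 -> means 42/34 -> 8/76
        g1 = AnnotatedGenome("a", "A" * 40 + "T" * 36 + "G" * 12 + "C" * 12,
                             taxon={"subfamily": "X"})
        g2 = AnnotatedGenome("b", "A" * 44 + "T" * 32 + "G" * 12 + "C" * 12,
                             taxon={"subfamily": "X"})
        df = group_summary([g1, g2], "subfamily")
        assert df.loc["X", "AT-skew"] == pytest.approx(8 / 76)

    def test_identical_members_equal_group(self):
        g1 = self._mk(7, "B")
        g2 = AnnotatedGenome("copy", g1.sequence, True, list(g1.features), dict(g1.taxon))
        df = group_summary([g1, g2], "subfamily")
        assert df.loc["B", "AT-skew"] == pytest.approx(base_composition(g1.sequence).at_skew)

    def test_modes_agree_for_equal_lengths(self):
        gs = [self._mk(s, "C") for s in (3, 4)]
        a = group_summary(gs, "subfamily", mode="mean_percent")
        b = group_summary(gs, "subfamily", mode="pooled")
        assert a.loc["C", "AT-skew"] == pytest.approx(b.loc["C", "AT-skew"], abs=2e-3)

    def test_unknown_key_raises(self):
        with pytest.raises(KeyError):
            group_summary([self._mk(1, "A")], "genus")
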