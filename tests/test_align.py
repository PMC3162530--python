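"""The spliced aligner against forced values and the enumeration oracle."""

import random

import pytest

from exonweaver.align import align_spliced
from exonweaver.errors import InputError
from exonweaver.oracle import enumerate_parses
from exonweaver.parse import Category, parse_cost
from exonweaver.penalties import PenaltyScheme

GT_INTRON = "GT" + "C" * 18 + "AG"
AA = "ACDEFGHIKLMNPQRSTVWY"


class TestForcedValues:
    def test_perfect_two_codon_exon_costs_zero(self, scheme):
        parse = align_spliced("MK", "ATGAAA", scheme)
        assert parse.cost == 0.0
        assert [s.category for s in parse.segments] == [Category.CODON_MATCH] * 2

    def test_one_canonical_intron_costs_exactly_its_base_penalty(self, scheme):
        parse = align_spliced("MK", "ATG" + GT_INTRON + "AAA", scheme)
        assert parse.cost == 2.0
        cats = [s.category for s in parse.segments]
        assert cats == [Category.CODON_MATCH, Category.INTRON, Category.CODON_MATCH]

    def test_lone_unmatched_residue_costs_insertion_penalty(self, scheme):
        parse = align_spliced("M", "", scheme)
        assert parse.cost == 1.5
        assert [s.category for s in parse.segments] == [Category.INSERTION]

    def test_lone_extra_codon_costs_gap_penalty(self, scheme):
        parse = align_spliced("", "ATG", scheme)
        assert parse.cost == pytest.approx(1.1)
        assert [s.category for s in parse.segments] == [Category.GAP]

    def test_extra_nucleotide_resolved_by_frameshift(self, scheme):
        assert align_spliced("M", "ATGC", scheme).cost == 2.5

    def test_empty_inputs_give_empty_parse(self, scheme):
        parse = align_spliced("", "", scheme)
        assert parse.cost == 0.0 and parse.segments == ()


class TestOracleEquivalence:
    def test_enumeration_refuses_large_inputs(self, small_scheme):
        with pytest.raises(InputError):
            enumerate_parses("MKLM" + "A", "ATG", small_scheme)

    def test_matches_oracle_on_random_instances(self, small_scheme):
        rng = random.Random(20240917)
        for _ in range(200):
            q = "".join(rng.choice(AA) for _ in range(rng.randint(0, 3)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 40)))
            parse = align_spliced(q, t, small_scheme)
            assert parse.cost == pytest.approx(enumerate_parses(q, t, small_scheme))
            # the parse itself must be valid and re-cost to its own cost
            assert parse_cost(parse.segments, small_scheme) == pytest.approx(parse.cost)
            assert parse.query == q and parse.target == t

    def test_split_codon_instances_match_oracle(self, small_scheme):
        # hand-built cases where the optimum must split a codon
        omega = "GTAAG"  # 5 nt at the reduced minimum
        for split in (1, 2):
            codon = "ATG"
            t = codon[:split] + omega + codon[split:]
            parse = align_spliced("M", t, small_scheme)
            assert parse.cost == pytest.approx(enumerate_parses("M", t, small_scheme))
            assert parse.cost == pytest.approx(2.0)
            assert parse.segments[0].category is Category.SPLIT_CODON_INTRON
            assert parse.segments[0].split_position == split


class TestInvariants:
    def test_zero_law_exact_spelling_costs_zero(self, scheme):
        rng = random.Random(7)
        from exonweaver.translate import codons_for

        q = "".join(rng.choice(AA) for _ in range(30))
        t = "".join(rng.choice(codons_for(aa)) for aa in q)
        parse = align_spliced(q, t, scheme)
        assert parse.cost == 0.0
        assert all(s.category is Category.CODON_MATCH for s in parse.segments)

    def test_intron_law_one_intron_adds_exactly_base_penalty(self, scheme):
        rng = random.Random(8)
        from exonweaver.translate import codons_for

        q = "".join(rng.choice(AA) for _ in range(20))
        codons = [rng.choice(codons_for(aa)) for aa in q]
        intron = "GT" + "".join(rng.choice("ACT") for _ in range(30)) + "AG"
        t = "".join(codons[:10]) + intron + "".join(codons[10:])
        assert align_spliced(q, t, scheme).cost == pytest.approx(
            scheme.intron_base_penalty
        )

    def test_single_substitution_bounded_cost_change(self, scheme):
        base = align_spliced("MKL", "ATGAAACTG", scheme).cost
        worst = max(
            align_spliced("MKL", "ATGAAACTG"[:i] + c + "ATGAAACTG"[i + 1 :], scheme).cost
            for i in range(9)
            for c in "ACGT"
        )
        bound = max(scheme.mismatch_penalty, scheme.frameshift_penalty + scheme.gap_penalty)
        assert worst - base <= bound

    def test_no_admissible_donor_below_min_intron_len(self):
        # target shorter than one codon + minimal intron: no intron segment possible
        s = PenaltyScheme(min_intron_len=10)
        parse = align_spliced("M", "ATG" + "GTCCCCCAG", s)  # 9-nt would-be intron
        assert not any(
            seg.category in (Category.INTRON, Category.SPLIT_CODON_INTRON)
            for seg in parse.segments
        )

    def test_determinism(self, scheme):
        a = align_spliced("MKWL", "ATGAAA" + GT_INTRON + "TGGCTG", scheme)
        b = align_spliced("MKWL", "ATGAAA" + GT_INTRON + "TGGCTG", scheme)
        assert a == b
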