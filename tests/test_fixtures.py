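"""The synthetic-fixture generator: determinism and truth self-consistency."""

import pytest

from exonweaver import (
    apply_divergence,
    fragment_into_contigs,
    generate_gene,
    inject_errors,
)
from exonweaver.errors import InputError
from exonweaver.translate import translate_cds


def spliced_cds(fix, part_idx=0):
    part = fix.parts[part_idx]
    genome = dict(fix.contigs)[part.target_id]
    return "".join(genome[e.tstart : e.tend] for e in part.exons)


class TestGenerateGene:
    def test_intronless_gene_contains_exact_codon_spelling(self):
        fix = generate_gene(seed=2, protein_length=50, n_introns=0)
        assert translate_cds(spliced_cds(fix)) == fix.protein

    def test_requested_phases_produce_matching_split_codons(self):
        fix = generate_gene(seed=3, protein_length=150, n_introns=3, phases=(0, 1, 2))
        assert [i.phase for i in fix.truth.introns] == [0, 1, 2]
        # splicing the introns out must reconstitute the protein exactly
        assert translate_cds(spliced_cds(fix)) == fix.protein

    def test_same_seed_is_deterministic(self):
        a = generate_gene(seed=77, protein_length=90, n_introns=2)
        b = generate_gene(seed=77, protein_length=90, n_introns=2)
        assert a.contigs == b.contigs and a.protein == b.protein

    def test_border_patterns_respected(self):
        fix = generate_gene(
            seed=5, protein_length=90, n_introns=2,
            border_patterns=(("GC", "AG"), ("AT", "AC")),
        )
        genome = fix.contigs[0][1]
        for intron, (d, a) in zip(fix.truth.introns, [("GC", "AG"), ("AT", "AC")]):
            assert genome[intron.tstart : intron.tstart + 2] == d
            assert genome[intron.tend - 2 : intron.tend] == a

    def test_exon_lengths_must_partition_protein(self):
        with pytest.raises(InputError):
            generate_gene(seed=1, protein_length=50, n_introns=1, exon_lengths=[10, 20])


class TestApplyDivergence:
    def test_rate_zero_is_identity(self):
        fix = generate_gene(seed=8, protein_length=100, n_introns=1)
        div = apply_divergence(fix, aa_substitution_rate=0.0, seed=1)
        assert div.contigs == fix.contigs

    def test_substitution_count_matches_recorded_truth(self):
        fix = generate_gene(seed=8, protein_length=300, n_introns=2)
        div = apply_divergence(fix, aa_substitution_rate=0.2, seed=9)
        n = len(div.substitutions)
        # binomial(≈300, 0.2): allow a generous window around the mean of 60
        assert 30 <= n <= 95
        assert div.parts[0].mismatches == sorted(div.substitutions)
        # every recorded substitution really mismatches, all others still match
        part = div.parts[0]
        genome = div.contigs[0][1]
        translated = translate_cds(
            "".join(genome[e.tstart : e.tend] for e in part.exons)
        )
        diff = [i for i, (a, b) in enumerate(zip(translated, div.protein)) if a != b]
        assert diff == sorted(div.substitutions)


class TestFragmentation:
    def test_no_breakpoints_is_passthrough(self):
        fix = generate_gene(seed=8, protein_length=100, n_introns=1)
        frag = fragment_into_contigs(fix, [])
        assert frag.contigs[0][1] == fix.contigs[0][1]

    def test_break_inside_intron_spans_two_contigs(self):
        fix = generate_gene(seed=13, protein_length=160, n_introns=3, phases=(0, 0, 0))
        mid = fix.truth.introns[1]
        frag = fragment_into_contigs(fix, [(mid.tstart + mid.tend) // 2])
        assert len(frag.contigs) == 2
        assert len(frag.parts) == 2
        assert "".join(c[1] for c in frag.contigs) == fix.contigs[0][1]
        # per-contig truth still translates to the protein
        combined = "".join(spliced_cds(frag, i) for i in range(2))
        assert translate_cds(combined) == frag.protein

    def test_break_inside_exon_rejected(self):
        fix = generate_gene(seed=8, protein_length=100, n_introns=1)
        exon = fix.truth.exons[0]
        with pytest.raises(InputError):
            fragment_into_contigs(fix, [(exon.tstart + exon.tend) // 2])

    def test_padding_grows_implied_join(self):
        fix = generate_gene(seed=13, protein_length=160, n_introns=3, phases=(0, 0, 0))
        mid = fix.truth.introns[1]
        bp = (mid.tstart + mid.tend) // 2
        plain = fragment_into_contigs(fix, [bp])
        padded = fragment_into_contigs(fix, [bp], pads=[(40000, 40000)])
        assert padded.joins[0] == plain.joins[0] + 80000


class TestInjectErrors:
    def test_zero_errors_is_identity(self):
        fix = generate_gene(seed=8, protein_length=100, n_introns=1)
        err = inject_errors(fix, 0, 0, seed=4)
        assert err.contigs == fix.contigs

    def test_counts_recorded_in_truth(self):
        fix = generate_gene(seed=8, protein_length=200, n_introns=2)
        err = inject_errors(fix, n_frameshifts=2, n_inframe_stops=1, seed=4)
        assert len(err.parts[0].frameshifts) == 2
        assert len(err.parts[0].stops) == 1
        # genome shrank by one nucleotide per frameshift deletion
        assert len(err.contigs[0][1]) == len(fix.contigs[0][1]) - 2
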