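import random

from exonweaver.fixtures import generate_gene
from exonweaver.seeds import seed_hits
from exonweaver.translate import revcomp, translate_codon


def test_intronless_exact_gene_yields_single_covering_block():
    fix = generate_gene(seed=5, protein_length=60, n_introns=0)
    hits = seed_hits(fix.protein, fix.query_id, fix.contigs, tilesize=7)
    assert len(hits) == 1
    (hit,) = hits
    assert hit.strand == "+"
    assert len(hit.blocks) == 1
    block = hit.blocks[0]
    assert (block.qstart, block.qend) == (0, 60)
    exon = fix.truth.exons[0]
    assert (block.tstart, block.tend) == (exon.tstart, exon.tend)


def test_two_intron_gene_yields_three_collinear_blocks(three_intron_fixture):
    fix = generate_gene(seed=9, protein_length=120, n_introns=2, phases=(0, 0))
    hits = seed_hits(fix.protein, fix.query_id, fix.contigs, tilesize=7)
    assert len(hits) >= 1
    blocks = hits[0].blocks
    assert len(blocks) >= 3
    # collinearity is a SeedHit invariant; verify every block is a true match run
    genome = dict(fix.contigs)[hits[0].target_id]
    for b in blocks:
        matched = sum(
            1
            for k in range(b.qend - b.qstart)
            if translate_codon(genome[b.tstart + 3 * k : b.tstart + 3 * k + 3])
            == fix.protein[b.qstart + k]
        )
        assert matched >= min(7, b.qend - b.qstart)


def test_unrelated_sequences_yield_nothing():
    rng = random.Random(13)
    protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(80))
    dna = "".join(rng.choice("ACGT") for _ in range(2000))
    assert seed_hits(protein, "q", [("t", dna)], tilesize=7) == []


def test_reverse_complement_mirrors_coordinates():
    fix = generate_gene(seed=21, protein_length=90, n_introns=1, phases=(0,))
    cid, seq = fix.contigs[0]
    fwd = seed_hits(fix.protein, "q", [(cid, seq)], tilesize=7)
    rev = seed_hits(fix.protein, "q", [(cid, revcomp(seq))], tilesize=7)
    assert [h.strand for h in fwd] == ["+"]
    assert [h.strand for h in rev] == ["-"]
    # processing-strand coordinates must be identical: the reverse hit works
    # on the reverse complement of the reverse-complemented contig
    assert [
        (b.qstart, b.qend, b.tstart, b.tend) for b in fwd[0].blocks
    ] == [(b.qstart, b.qend, b.tstart, b.tend) for b in rev[0].blocks]


def test_empty_inputs():
    assert seed_hits("", "q", [("t", "ACGT" * 100)]) == []
    assert seed_hits("MKLMKLMKL", "q", []) == []
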