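import pytest

from exonweaver.errors import InvalidParseError
from exonweaver.parse import Category, SegmentPair, make_parse, parse_cost

GT_INTRON = "GT" + "C" * 18 + "AG"


def seg(cat, q, t, omega="", sp=0):
    return SegmentPair(cat, q, t, intron_subsequence=omega, split_position=sp)


class TestParseCost:
    def test_empty_parse_costs_zero(self, scheme):
        assert parse_cost([], scheme) == 0.0

    def test_exact_codon_matches_cost_zero(self, scheme):
        segs = [seg(Category.CODON_MATCH, "M", "ATG"), seg(Category.CODON_MATCH, "K", "AAA")]
        assert parse_cost(segs, scheme) == 0.0

    def test_exon_intron_exon_costs_intron_penalty(self, scheme):
        segs = [
            seg(Category.CODON_MATCH, "M", "ATG"),
            seg(Category.INTRON, "", GT_INTRON),
            seg(Category.CODON_MATCH, "K", "AAA"),
        ]
        assert parse_cost(segs, scheme) == 2.0

    def test_split_codon_intron_reassembles_codon(self, scheme):
        # codon ATG split after 1 nt: A | omega | TG
        segs = [seg(Category.SPLIT_CODON_INTRON, "M", "A" + GT_INTRON + "TG", GT_INTRON, 1)]
        assert parse_cost(segs, scheme) == 2.0

    def test_mixed_categories_sum(self, scheme):
        segs = [
            seg(Category.INSERTION, "M", ""),
            seg(Category.GAP, "", "ATG"),
            seg(Category.FRAMESHIFT, "", "AT"),
        ]
        assert parse_cost(segs, scheme) == pytest.approx(1.5 + 1.1 + 2.5)


class TestInvalidSegments:
    @pytest.mark.parametrize(
        "segment",
        [
            seg(Category.CODON_MATCH, "MK", "ATGAAA"),  # two residues in one segment
            seg(Category.CODON_MATCH, "M", "ATGA"),  # four-nt codon
            seg(Category.INSERTION, "M", "A"),  # insertion may not consume target
            seg(Category.GAP, "", "AT"),  # gap must be a full codon
            seg(Category.FRAMESHIFT, "", "ATG"),  # three nt is a codon, not a frameshift
            seg(Category.INTRON, "", "GT" + "C" * 17 + "AG"),  # below minimum length
            seg(Category.INTRON, "M", GT_INTRON),  # plain introns carry no residue
            seg(Category.SPLIT_CODON_INTRON, "M", "A" + GT_INTRON + "TG", GT_INTRON, 3),
        ],
    )
    def test_raises(self, segment, scheme):
        with pytest.raises(InvalidParseError):
            parse_cost([segment], scheme)


def test_parse_concatenation_reproduces_inputs(scheme):
    segs = (
        seg(Category.CODON_MATCH, "M", "ATG"),
        seg(Category.INSERTION, "K", ""),
        seg(Category.INTRON, "", GT_INTRON),
        seg(Category.GAP, "", "CCC"),
    )
    parse = make_parse(segs, scheme)
    assert parse.query == "MK"
    assert parse.target == "ATG" + GT_INTRON + "CCC"
    assert parse.cost == pytest.approx(1.5 + 2.0 + 1.1)
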