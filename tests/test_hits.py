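import pytest

from exonweaver.errors import InputError
from exonweaver.hits import Block, SeedHit, compute_stats, filter_hits, hit_stats


def make_hit(blocks, qid="q", tid="t"):
    return SeedHit(query_id=qid, target_id=tid, strand="+", blocks=tuple(blocks))


class TestComputeStats:
    def test_partial_hit(self):
        st = compute_stats(55, 5, 100)
        assert st.coverage == pytest.approx(0.60)
        assert st.identity == pytest.approx(55 / 60)
        assert st.score == pytest.approx(0.50)

    def test_perfect_full_length_hit(self):
        st = compute_stats(100, 0, 100)
        assert st.coverage == 1.0 and st.identity == 1.0 and st.score == 1.0

    def test_no_mapped_residues(self):
        st = compute_stats(0, 0, 100)
        assert st.coverage == 0.0 and st.identity == 0.0

    def test_score_clipped_at_zero(self):
        assert compute_stats(10, 40, 100).score == 0.0

    def test_requires_positive_query_length(self):
        with pytest.raises(InputError):
            compute_stats(1, 0, 0)


class TestFilterHits:
    def test_coverage_boundary_is_inclusive(self):
        at = make_hit([Block(0, 60, 0, 180, matches=60)])
        below = make_hit([Block(0, 50, 0, 150, matches=50)])
        kept = filter_hits([at, below], 100, min_score=0.0, min_identity=0.0)
        assert kept == [at]

    def test_empty_input(self):
        assert filter_hits([], 100) == []

    def test_identity_and_mismatch_thresholds(self):
        noisy = make_hit([Block(0, 100, 0, 300, matches=80, mismatches=20)])
        assert filter_hits([noisy], 100, min_identity=0.9) == []
        assert filter_hits([noisy], 100, min_identity=0.6, max_mismatch=10) == []
        assert filter_hits([noisy], 100, min_identity=0.6, max_mismatch=None, min_score=0.3) == [noisy]


class TestInvariants:
    def test_block_span_ratio_enforced(self):
        with pytest.raises(InputError):
            Block(0, 10, 0, 29)

    def test_blocks_must_increase_in_both_coordinates(self):
        with pytest.raises(InputError):
            make_hit([Block(0, 10, 0, 30), Block(5, 15, 60, 90)])
        with pytest.raises(InputError):
            make_hit([Block(0, 10, 60, 90), Block(10, 20, 0, 30)])

    def test_hit_stats_sums_blocks(self):
        hit = make_hit(
            [Block(0, 10, 0, 30, matches=9, mismatches=1),
             Block(12, 20, 90, 114, matches=8)]
        )
        st = hit_stats(hit, 40)
        assert (st.matches, st.mismatches) == (17, 1)
        assert st.coverage == pytest.approx(18 / 40)
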