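"""Cross-contig composition and final result selection."""

import pytest

from exonweaver import (
    SearchParams,
    evaluate_recovery,
    fragment_into_contigs,
    generate_gene,
    map_query,
    with_paralog,
)
from exonweaver.assembly import assemble_across_targets, select_final_results


@pytest.fixture(scope="module")
def split_gene():
    fix = generate_gene(
        seed=13, protein_length=160, n_introns=3, phases=(0, 0, 0),
        intron_length_range=(100, 300),
    )
    mid = fix.truth.introns[1]
    return fix, fragment_into_contigs(fix, [(mid.tstart + mid.tend) // 2])


FRAG_PARAMS = dict(min_coverage=0.0, min_score=0.05)


class TestComposition:
    def test_two_contig_gene_reassembles_exactly(self, split_gene):
        _, frag = split_gene
        res = map_query(frag.query_id, frag.protein, frag.contigs, SearchParams(**FRAG_PARAMS))
        assert evaluate_recovery(res, frag)["structure_exact"]
        assert res[0].targets_used == [c[0] for c in frag.contigs]
        assert res[0].joins == frag.joins

    def test_three_contig_gene_reassembles_exactly(self):
        fix = generate_gene(
            seed=21, protein_length=240, n_introns=4, phases=(0, 0, 0, 0),
            intron_length_range=(150, 400),
        )
        i1, i3 = fix.truth.introns[0], fix.truth.introns[3]
        frag = fragment_into_contigs(
            fix, [(i1.tstart + i1.tend) // 2, (i3.tstart + i3.tend) // 2]
        )
        res = map_query(frag.query_id, frag.protein, frag.contigs, SearchParams(**FRAG_PARAMS))
        assert evaluate_recovery(res, frag)["structure_exact"]
        assert len(res[0].parts) == 3

    def test_oversize_implied_intron_discards_lower_scoring_part(self, split_gene):
        fix, _ = split_gene
        mid = fix.truth.introns[1]
        frag = fragment_into_contigs(
            fix, [(mid.tstart + mid.tend) // 2], pads=[(40000, 40000)]
        )
        assert frag.joins[0] > 75000
        res = map_query(frag.query_id, frag.protein, frag.contigs, SearchParams(**FRAG_PARAMS))
        assert len(res) == 1 and len(res[0].parts) == 1
        # the kept part is the higher-scoring one
        scores = {p.target_id: p.stats.score for p in frag.parts}
        assert res[0].parts[0].target_id == max(scores, key=scores.get)

    def test_oversize_join_with_multiple_results_keeps_both_sides(self, split_gene):
        fix, _ = split_gene
        mid = fix.truth.introns[1]
        frag = fragment_into_contigs(
            fix, [(mid.tstart + mid.tend) // 2], pads=[(40000, 40000)]
        )
        res = map_query(
            frag.query_id, frag.protein, frag.contigs,
            SearchParams(multiple_results=True, **FRAG_PARAMS),
        )
        assert {p.target_id for r in res for p in r.parts} == {c[0] for c in frag.contigs}

    def test_single_target_hits_never_joins_contigs(self, split_gene):
        _, frag = split_gene
        res = map_query(
            frag.query_id, frag.protein, frag.contigs,
            SearchParams(single_target_hits=True, **FRAG_PARAMS),
        )
        assert all(len(r.parts) == 1 for r in res)

    def test_single_contig_passthrough(self, three_intron_fixture, default_params):
        fix = three_intron_fixture
        res = map_query(fix.query_id, fix.protein, fix.contigs, default_params)
        assert len(res) == 1 and len(res[0].parts) == 1 and res[0].joins == []


class TestSelection:
    def test_multiple_results_reports_paralogs_separately(self):
        fix = generate_gene(seed=17, protein_length=120, n_introns=2)
        par = with_paralog(fix, divergence=0.05, seed=3)
        params = SearchParams(
            multiple_results=True, single_target_hits=True, min_identity=0.6
        )
        res = map_query(par.query_id, par.protein, par.contigs, params)
        assert len(res) == 2
        assert res[0].stats.score >= res[1].stats.score
        assert {r.parts[0].target_id for r in res} == {c[0] for c in par.contigs}

    def test_best_only_without_multiple_results(self):
        fix = generate_gene(seed=17, protein_length=120, n_introns=2)
        par = with_paralog(fix, divergence=0.05, seed=3)
        params = SearchParams(single_target_hits=True, min_identity=0.6)
        res = map_query(par.query_id, par.protein, par.contigs, params)
        assert len(res) == 1
        assert res[0].parts[0].target_id == fix.contigs[0][0]

    def test_no_passing_candidate_gives_empty_result(self):
        fix = generate_gene(seed=17, protein_length=120, n_introns=2)
        res = map_query(fix.query_id, fix.protein, fix.contigs, SearchParams(min_score=0.999999))
        assert res == [] or res[0].stats.score >= 0.999999

    def test_min_dna_coverage_rejects_sprawling_composition(self, split_gene):
        _, frag = split_gene
        parts = [
            p
            for r in map_query(
                frag.query_id, frag.protein, frag.contigs,
                SearchParams(single_target_hits=True, multiple_results=True, **FRAG_PARAMS),
            )
            for p in r.parts
        ]
        qlen = len(frag.protein)
        composed = assemble_across_targets(parts, qlen, min_dna_coverage=0.0)
        assert len(composed[0].parts) == 2
        strict = assemble_across_targets(parts, qlen, min_dna_coverage=99.0)
        assert len(strict[0].parts) == 1

    def test_results_never_interleave_query_spans(self, split_gene):
        _, frag = split_gene
        res = map_query(frag.query_id, frag.protein, frag.contigs, SearchParams(**FRAG_PARAMS))
        for r in res:
            spans = [(p.qstart, p.qend) for p in r.parts]
            assert spans == sorted(spans)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
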