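"""High-level search driver: seed, filter, refine, assemble, select."""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

from .assembly import assemble_across_targets, select_final_results
from .hits import SeedHit, filter_hits, rescore_hit
from .params import SearchParams
from .pipeline import refine_hit
from .seeds import densify_hit, seed_hits
from .structure import GeneResult
from .translate import revcomp

logger = logging.getLogger(__name__)


def processing_sequence(contig_seq: str, strand: str) -> str:
    """The strand the pipeline works on: reverse complement for minus hits."""
    return contig_seq if strand == "+" else revcomp(contig_seq)


def map_query(
    query_id: str,
    query: str,
    targets: Sequence[Tuple[str, str]],
    params: Optional[SearchParams] = None,
    hits: Optional[Sequence[SeedHit]] = None,
) -> List[GeneResult]:
    """Map one protein query onto a set of contigs.

    ``hits`` may carry externally produced seed alignments (e.g. from PSL
    input); otherwise the built-in translated k-mer seeder runs.  Returns the
    selected results, best first.
    """
    params = params or SearchParams()
    query = query.upper()
    contig = {tid: seq.upper() for tid, seq in targets}
    if hits is None:
        hits = seed_hits(
            query,
            query_id,
            targets,
            tilesize=params.tilesize,
            table_id=params.transtable,
            max_target_gap=params.max_assemble_size,
        )
    proc_cache: Dict[Tuple[str, str], str] = {}

    def proc(hit: SeedHit) -> str:
        key = (hit.target_id, hit.strand)
        if key not in proc_cache:
            proc_cache[key] = processing_sequence(contig[hit.target_id], hit.strand)
        return proc_cache[key]

    hits = [rescore_hit(h, query, proc(h), params.transtable) for h in hits]
    hits = filter_hits(
        hits,
        len(query),
        min_score=params.min_score,
        min_identity=params.min_identity,
        max_mismatch=params.max_mismatch,
        min_coverage=params.min_coverage,
    )
    hits = [
        densify_hit(
            h,
            query,
            proc(h),
            params.transtable,
            exhaust_gap_size=params.exhaust_gap_size,
            gap_to_close=params.gap_to_close,
            flank_window=params.exhaust_align_size,
        )
        for h in hits
    ]
    hits = [rescore_hit(h, query, proc(h), params.transtable) for h in hits]
    parts = [refine_hit(h, query, proc(h), params) for h in hits]
    if params.single_target_hits:
        candidates = [
            assemble_across_targets([p], len(query), multiple_results=False)[0]
            for p in parts
        ]
    else:
        candidates = assemble_across_targets(
            parts,
            len(query),
            max_assemble_size=params.max_assemble_size,
            min_dna_coverage=params.min_dna_coverage,
            multiple_results=params.multiple_results,
        )
    return select_final_results(candidates, params)


def run_search(
    queries: Sequence[Tuple[str, str]],
    targets: Sequence[Tuple[str, str]],
    params: Optional[SearchParams] = None,
    psl_hits: Optional[Sequence[SeedHit]] = None,
) -> Dict[str, List[GeneResult]]:
    """Map every query; returns an ordered mapping query id -> results."""
    params = params or SearchParams()
    out: Dict[str, List[GeneResult]] = {}
    for qid, qseq in queries:
        hits = None
        if psl_hits is not None:
            hits = [h for h in psl_hits if h.query_id == qid]
        out[qid] = map_query(qid, qseq, targets, params, hits=hits)
        logger.info("%s: %d result(s)", qid, len(out[qid]))
    return out
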