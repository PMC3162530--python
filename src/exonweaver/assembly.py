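"""Composition of partial gene structures across contigs, and final selection.

Fragmented assemblies often split one gene over several contigs; partial
structures that cover disjoint, ordered parts of the query are chained into a
composed hit as long as the intron implied between two contigs (distance from
the last exon to the contig end, plus the offset of the first exon on the
next contig) stays within ``max_assemble_size``.  On chromosome-scale
targets this behaviour is disabled (``single_target_hits``), which prevents
spurious joins of a short chance match on another chromosome.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

from .hits import compute_stats
from .params import SearchParams
from .structure import GeneResult, GeneStructure

logger = logging.getLogger(__name__)


#: parts may overlap by up to this many query residues; the lower-scoring
#: side is trimmed (seed extensions can creep a few residues across a contig
#: break by chance)
MAX_PART_OVERLAP = 6


def _implied_join(a: GeneStructure, b: GeneStructure) -> int:
    return (a.target_length - a.tend) + b.tstart


def _copy_part(p: GeneStructure) -> GeneStructure:
    import copy

    return copy.deepcopy(p)


def _trim_part_head(p: GeneStructure, k: int, query_length: int) -> bool:
    first = p.exons[0]
    if first.qend - first.qstart <= k:
        return False
    first.qstart += k
    first.tstart += 3 * k
    old_mism = len(p.mismatches)
    p.mismatches = [m for m in p.mismatches if m >= first.qstart]
    p.stops = [s for s in p.stops if s >= first.qstart]
    removed_mism = old_mism - len(p.mismatches)
    p.stats = compute_stats(
        p.stats.matches - (k - removed_mism), len(p.mismatches), query_length
    )
    return True


def _trim_part_tail(p: GeneStructure, k: int, query_length: int) -> bool:
    last = p.exons[-1]
    if last.qend - last.qstart <= k:
        return False
    last.qend -= k
    last.tend -= 3 * k
    old_mism = len(p.mismatches)
    p.mismatches = [m for m in p.mismatches if m < last.qend]
    p.stops = [s for s in p.stops if s < last.qend]
    removed_mism = old_mism - len(p.mismatches)
    p.stats = compute_stats(
        p.stats.matches - (k - removed_mism), len(p.mismatches), query_length
    )
    return True


def _resolve_overlaps(
    chain: List[GeneStructure], query_length: int
) -> List[GeneStructure]:
    """Trim small query overlaps between adjacent parts (lower score yields)."""
    out = [chain[0]]
    for b in chain[1:]:
        a = out[-1]
        ov = a.qend - b.qstart
        if ov > 0:
            a2, b2 = _copy_part(a), _copy_part(b)
            # trim the side whose overlapping residues look worse (more
            # mismatches), falling back to the lower-scoring part
            a_bad = sum(1 for m in a.mismatches if m >= b.qstart)
            b_bad = sum(1 for m in b.mismatches if m < a.qend)
            if b_bad > a_bad or (b_bad == a_bad and b.stats.score <= a.stats.score):
                ok = _trim_part_head(b2, ov, query_length)
            else:
                ok = _trim_part_tail(a2, ov, query_length)
            if not ok:
                continue
            out[-1] = a2
            b = b2
        out.append(b)
    return out


def _mapped(p: GeneStructure) -> int:
    return p.stats.matches + p.stats.mismatches


def _subtract_intervals(span, covered):
    """Parts of ``span`` not covered by the sorted, merged ``covered`` list."""
    s, e = span
    pieces = []
    for cs, ce in covered:
        if ce <= s:
            continue
        if cs >= e:
            break
        if cs > s:
            pieces.append((s, cs))
        s = max(s, ce)
        if s >= e:
            break
    if s < e:
        pieces.append((s, e))
    return pieces


def _prune_covered_gaps(parts: List[GeneStructure]) -> List[GeneStructure]:
    """Trim per-part unmatched-query records to what no sibling part covers
    (each partial structure saw only its own contig)."""
    out = []
    for p in parts:
        covered = sorted(
            (e.qstart, e.qend) for q in parts if q is not p for e in q.exons
        )
        merged = []
        for iv in covered:
            if merged and iv[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
            else:
                merged.append(iv)
        kept = [piece for g in p.gaps for piece in _subtract_intervals(g, merged)]
        if kept != p.gaps:
            p = _copy_part(p)
            p.gaps = kept
        out.append(p)
    return out


def _result_from_parts(parts: List[GeneStructure], query_length: int) -> GeneResult:
    if len(parts) > 1:
        parts = _resolve_overlaps(parts, query_length)
        parts = _prune_covered_gaps(parts)
    joins = [_implied_join(a, b) for a, b in zip(parts, parts[1:])]
    matches = sum(p.stats.matches for p in parts)
    mism = sum(p.stats.mismatches for p in parts)
    span = sum(p.genomic_span for p in parts) + sum(joins)
    return GeneResult(
        query_id=parts[0].query_id,
        parts=parts,
        stats=compute_stats(matches, mism, query_length),
        joins=joins,
        dna_coverage=(100.0 * 3 * (matches + mism) / span) if span else 0.0,
    )


def _best_chain(
    parts: List[GeneStructure], max_assemble_size: int
) -> List[GeneStructure]:
    order = sorted(range(len(parts)), key=lambda i: (parts[i].qstart, parts[i].qend))
    score = [parts[i].stats.score for i in order]
    back = [-1] * len(order)
    for i in range(len(order)):
        pi = parts[order[i]]
        for j in range(i):
            pj = parts[order[j]]
            if (
                pj.qend <= pi.qstart + MAX_PART_OVERLAP
                and pj.qend < pi.qend
                and pj.target_id != pi.target_id
                and _implied_join(pj, pi) <= max_assemble_size
            ):
                cand = score[j] + pi.stats.score
                if cand > score[i]:
                    score[i] = cand
                    back[i] = j
    best = max(range(len(order)), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(parts[order[i]])
        i = back[i]
    chain.reverse()
    return chain


def assemble_across_targets(
    parts: Sequence[GeneStructure],
    query_length: int,
    max_assemble_size: int = 75000,
    min_dna_coverage: float = 0.0,
    multiple_results: bool = False,
) -> List[GeneResult]:
    """Chain partial structures into composed hits.

    The best-scoring compatible chain forms the primary result; parts that
    cannot join it (oversize implied introns, overlapping query spans) are
    returned as further results only when ``multiple_results`` is on —
    otherwise the lower-scoring side is discarded.  Compositions whose
    query/target length ratio falls below ``min_dna_coverage`` percent are
    decomposed until the constraint holds.
    """
    remaining = list(parts)
    results: List[GeneResult] = []
    while remaining:
        chain = _best_chain(remaining, max_assemble_size)
        while len(chain) > 1:
            res = _result_from_parts(chain, query_length)
            if min_dna_coverage <= 0 or res.dna_coverage >= min_dna_coverage:
                break
            drop = min(chain, key=lambda p: p.stats.score)
            logger.info(
                "composition below min_dna_coverage; dropping %s", drop.target_id
            )
            chain = [p for p in chain if p is not drop]
        results.append(_result_from_parts(chain, query_length))
        remaining = [p for p in remaining if p not in chain]
        if not multiple_results:
            break
    if multiple_results and remaining:
        results.extend(_result_from_parts([p], query_length) for p in remaining)
    results.sort(key=lambda r: (-r.stats.score, r.targets_used))
    return results


def select_final_results(
    candidates: Sequence[GeneResult], params: SearchParams
) -> List[GeneResult]:
    """Apply final thresholds and the single/multiple result policy."""
    passing = []
    for res in candidates:
        if res.stats.score < params.min_score:
            continue
        if res.stats.identity < params.min_identity:
            continue
        if params.max_mismatch is not None and res.stats.mismatches > params.max_mismatch:
            continue
        passing.append(res)
    passing.sort(key=lambda r: (-r.stats.score, r.targets_used))
    if not passing:
        logger.warning("no candidate passed the final thresholds")
        return []
    if params.multiple_results:
        return passing
    return passing[:1]
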