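"""Six-frame translated k-mer seeding with ungapped extension.

A self-contained stand-in for an external seed aligner: exact amino-acid
k-mers shared between the query and any of the six translated frames of a
contig are extended without gaps (tolerating isolated mismatches, stopping
after five consecutive ones and trimming mismatching ends), deduplicated per
diagonal, and chained into collinear hits.  External seed alignments in PSL
format can be ingested instead via :mod:`exonweaver.pslio`.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

from .hits import Block, SeedHit
from .translate import revcomp, translate_cds, translate_codon

#: X-drop extension scoring: +1 per match, -2 per mismatch; extension stops
#: once the running score falls this far below its maximum, and the block is
#: trimmed back to the maximum.  This tolerates divergent stretches (which
#: stay net-positive at realistic identity) while bounding how far an
#: extension can creep into intronic sequence on isolated chance matches.
XDROP = 6
_MISMATCH_STEP = -2


def _extend(
    query: str,
    frame_aa: str,
    qpos: int,
    tpos: int,
    k: int,
    mismatch_step: int = _MISMATCH_STEP,
    keep_ties: bool = False,
) -> Tuple[int, int]:
    """Extend an exact k-mer seed at (qpos, tpos) in both directions with
    X-drop trimming.  Returns the (qstart, qend) of the extension; target
    coordinates follow from the diagonal.

    ``mismatch_step``/``keep_ties`` select a more sensitive variant (used in
    small double-anchored rescue windows) that pushes through heavily
    diverged stretches where the default parameters would stop.
    """
    qe, te = qpos + k, tpos + k
    score, best, best_q = 0, 0, qe
    while qe < len(query) and te < len(frame_aa):
        score += 1 if query[qe] == frame_aa[te] else mismatch_step
        qe += 1
        te += 1
        if score > best or (keep_ties and score == best):
            best, best_q = score, qe
        elif best - score >= XDROP:
            break
    qe = best_q
    qs, ts = qpos, tpos
    score, best, best_q = 0, 0, qs
    while qs > 0 and ts > 0:
        score += 1 if query[qs - 1] == frame_aa[ts - 1] else mismatch_step
        qs -= 1
        ts -= 1
        if score > best or (keep_ties and score == best):
            best, best_q = score, qs
        elif best - score >= XDROP:
            break
    return best_q, qe


def _blocks_for_frame(
    query: str,
    frame_aa: str,
    kmer_index: Dict[str, List[int]],
    k: int,
    sensitive: bool = False,
) -> List[Tuple[int, int, int, int]]:
    """All distinct trimmed extensions in one frame as (qs, qe, ts_aa, matches)."""
    seen = set()
    out = []
    step = -1 if sensitive else _MISMATCH_STEP
    for p in range(len(frame_aa) - k + 1):
        positions = kmer_index.get(frame_aa[p : p + k])
        if not positions:
            continue
        for qpos in positions:
            diag = p - qpos
            qs, qe = _extend(
                query, frame_aa, qpos, p, k, mismatch_step=step, keep_ties=sensitive
            )
            key = (diag, qs, qe)
            if key in seen:
                continue
            seen.add(key)
            ts = qs + diag
            matches = sum(1 for a, b in zip(query[qs:qe], frame_aa[ts : ts + (qe - qs)]) if a == b)
            if matches >= min(k, qe - qs):
                out.append((qs, qe, ts, matches))
    return out


def _chain(blocks: List[Block], max_target_gap: int) -> List[List[Block]]:
    """Extract collinear chains greedily by decreasing chain weight."""
    chains = []
    remaining = sorted(blocks, key=lambda b: (b.qstart, b.tstart))
    while remaining:
        n = len(remaining)
        score = [b.matches - b.mismatches for b in remaining]
        back = [-1] * n
        for i in range(n):
            bi = remaining[i]
            for j in range(i):
                bj = remaining[j]
                if (
                    bj.qend <= bi.qstart
                    and bj.tend <= bi.tstart
                    and bi.tstart - bj.tend <= max_target_gap
                ):
                    cand = score[j] + bi.matches - bi.mismatches
                    if cand > score[i]:
                        score[i] = cand
                        back[i] = j
        best = max(range(n), key=lambda i: (score[i], -remaining[i].qstart))
        if score[best] <= 0:
            break
        chain = []
        i = best
        while i != -1:
            chain.append(remaining[i])
            i = back[i]
        chain.reverse()
        chains.append(chain)
        used_q = [(c.qstart, c.qend) for c in chain]
        used_t = [(c.tstart, c.tend) for c in chain]
        remaining = [
            b
            for b in remaining
            if b not in chain
            and not any(b.tstart < te and b.tend > ts for ts, te in used_t)
        ]
        if len(chains) >= 10:
            break
    return chains


#: rescue-pass seed length and minimum matches a rescued block must reach;
#: 3-mers are only safe because rescue windows are small and double-anchored
#: and short chance extensions cannot reach the match minimum
RESCUE_TILESIZE = 3
RESCUE_MIN_MATCHES = 5


def _window_blocks(
    query: str,
    q0: int,
    q1: int,
    proc: str,
    t0: int,
    t1: int,
    table_id: int,
    k: int = RESCUE_TILESIZE,
    sensitive: bool = True,
) -> List[Block]:
    """Seed query[q0:q1] against proc[t0:t1] with short k-mers; absolute
    coordinates.  Only blocks with a convincing number of matches survive
    (short seeds in small windows otherwise admit chance hits).  The
    sensitive extension mode is safe only in double-anchored windows; callers
    scanning an open terminal flank must switch it off."""
    sub_q = query[q0:q1]
    sub_t = proc[t0:t1]
    if len(sub_q) < k or len(sub_t) < 3 * k:
        return []
    kmer_index: defaultdict = defaultdict(list)
    for i in range(len(sub_q) - k + 1):
        kmer_index[sub_q[i : i + k]].append(i)
    out: List[Block] = []
    for frame in range(3):
        frame_aa = translate_cds(sub_t[frame:], table_id)
        if len(frame_aa) < k:
            continue
        for qs, qe, ts, matches in _blocks_for_frame(
            sub_q, frame_aa, dict(kmer_index), k, sensitive=sensitive
        ):
            if matches < RESCUE_MIN_MATCHES:
                continue
            out.append(
                Block(
                    qstart=q0 + qs,
                    qend=q0 + qe,
                    tstart=t0 + frame + 3 * ts,
                    tend=t0 + frame + 3 * (ts + (qe - qs)),
                    matches=matches,
                    mismatches=(qe - qs) - matches,
                )
            )
    return out


def densify_hit(
    hit: SeedHit,
    query: str,
    proc: str,
    table_id: int,
    exhaust_gap_size: int = 21,
    gap_to_close: int = 6,
    flank_window: int = 15000,
) -> SeedHit:
    """Second seeding pass inside a hit's oversized gaps.

    Query gaps wider than ``exhaust_gap_size`` would stay unresolved (the
    exhaustive aligner refuses them), so the bounded windows between the
    flanking blocks — and the terminal flanks, for unmatched termini beyond
    ``gap_to_close`` — are re-seeded with short k-mers.  Divergent exons the
    primary pass missed are recovered; the windows are small enough that
    chance blocks are filtered by the match minimum.
    """
    blocks = list(hit.blocks)
    extra: List[Block] = []
    for L, R in zip(blocks, blocks[1:]):
        gq = R.qstart - L.qend
        if gq > exhaust_gap_size and R.tstart - L.tend >= 3 * gq:
            extra.extend(
                _window_blocks(query, L.qend, R.qstart, proc, L.tend, R.tstart, table_id)
            )
    g = blocks[0].qstart
    if g > gap_to_close:
        t1 = blocks[0].tstart
        extra.extend(
            _window_blocks(
                query, 0, g, proc, max(0, t1 - flank_window), t1, table_id,
                sensitive=False,
            )
        )
    g = len(query) - blocks[-1].qend
    if g > gap_to_close:
        t0 = blocks[-1].tend
        extra.extend(
            _window_blocks(
                query, len(query) - g, len(query), proc,
                t0, min(len(proc), t0 + flank_window), table_id,
                sensitive=False,
            )
        )
    if not extra:
        return hit
    merged = _resolve_block_overlaps(blocks + extra, query, proc, table_id)
    chains = _chain(merged, max_target_gap=max(flank_window, 75000))
    if not chains:
        return hit
    best = max(chains, key=lambda c: sum(b.matches - b.mismatches for b in c))
    return SeedHit(
        query_id=hit.query_id,
        target_id=hit.target_id,
        strand=hit.strand,
        blocks=tuple(best),
        target_length=hit.target_length,
    )


def seed_hits(
    query: str,
    query_id: str,
    targets: Sequence[Tuple[str, str]],
    tilesize: int = 7,
    table_id: int = 1,
    max_target_gap: int = 75000,
) -> List[SeedHit]:
    """Deterministic seed hits of ``query`` against every contig, both strands.

    Returns one hit per collinear chain (several per contig when a contig
    carries more than one gene copy), ordered by contig, strand and position.
    """
    query = query.upper()
    k = tilesize
    if len(query) < k or not targets:
        return []
    kmer_index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(query) - k + 1):
        kmer_index[query[i : i + k]].append(i)
    hits: List[SeedHit] = []
    for target_id, seq in targets:
        seq = seq.upper()
        for strand in "+-":
            proc = seq if strand == "+" else revcomp(seq)
            raw_blocks: List[Block] = []
            for frame in range(3):
                frame_aa = translate_cds(proc[frame:], table_id)
                if len(frame_aa) < k:
                    continue
                for qs, qe, ts, matches in _blocks_for_frame(query, frame_aa, kmer_index, k):
                    raw_blocks.append(
                        Block(
                            qstart=qs,
                            qend=qe,
                            tstart=frame + 3 * ts,
                            tend=frame + 3 * (ts + (qe - qs)),
                            matches=matches,
                            mismatches=(qe - qs) - matches,
                        )
                    )
            if not raw_blocks:
                continue
            raw_blocks = _resolve_block_overlaps(raw_blocks, query, proc, table_id)
            for chain in _chain(raw_blocks, max_target_gap):
                hits.append(
                    SeedHit(
                        query_id=query_id,
                        target_id=target_id,
                        strand=strand,
                        blocks=tuple(chain),
                        target_length=len(seq),
                    )
                )
    hits.sort(key=lambda h: (h.target_id, h.strand, h.blocks[0].tstart))
    return hits


def _trim_head(b: Block, k: int) -> Block:
    return Block(
        qstart=b.qstart + k,
        qend=b.qend,
        tstart=b.tstart + 3 * k,
        tend=b.tend,
        matches=max(0, b.matches - k),
        mismatches=b.mismatches,
    )


def _trim_tail(b: Block, k: int) -> Block:
    return Block(
        qstart=b.qstart,
        qend=b.qend - k,
        tstart=b.tstart,
        tend=b.tend - 3 * k,
        matches=max(0, b.matches - k),
        mismatches=b.mismatches,
    )


#: largest block overlap (residues) resolved by trimming; larger overlaps are
#: left to chaining (they usually indicate repeats/paralogs, not creep)
MAX_OVERLAP_TRIM = 15


def _resolve_block_overlaps(
    blocks: List[Block], query: str, proc: str, table_id: int
) -> List[Block]:
    """Trim small query or target overlaps between target-ordered neighbours.

    Mismatch-tolerant extensions can creep a few residues across an exon
    border into intronic sequence (or across a small indel, shifting the
    diagonal); the creeping side is recognisable because its overlapping
    residues barely match, and is trimmed — or dropped when nothing remains —
    so that the true neighbouring block can be chained.  Junction
    realignment later restores the exact boundary.
    """

    def region_matches(b: Block, qs: int, qe: int) -> int:
        n = 0
        for q in range(max(qs, b.qstart), min(qe, b.qend)):
            t = b.tstart + 3 * (q - b.qstart)
            if translate_codon(proc[t : t + 3], table_id) == query[q]:
                n += 1
        return n

    blocks = sorted(blocks, key=lambda b: (b.tstart, b.qstart))
    out: List[Block] = []
    for b in blocks:
        while out is not None and out:
            prev = out[-1]
            q_ov = prev.qend - b.qstart
            if prev.tend <= b.tstart and 0 < q_ov <= MAX_OVERLAP_TRIM:
                pm = region_matches(prev, b.qstart, prev.qend)
                bm = region_matches(b, b.qstart, prev.qend)
                if pm > bm or (pm == bm and b.qend - b.qstart > q_ov):
                    if b.qend - b.qstart > q_ov:
                        b = _trim_head(b, q_ov)
                    else:
                        b = None  # nothing real remains of the later block
                else:
                    if prev.qend - prev.qstart > q_ov:
                        out[-1] = _trim_tail(prev, q_ov)
                    else:
                        out.pop()
                        continue  # re-examine against the new last block
                break
            t_ov = prev.tend - b.tstart
            k = -(-t_ov // 3)
            if (
                b.qstart >= prev.qend
                and 0 < t_ov <= 18
                and k < prev.qend - prev.qstart
            ):
                out[-1] = _trim_tail(prev, k)
            break
        if b is not None:
            out.append(b)
    return out
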