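"""Refinement of seed hits into gene structures.

The stages, in order: hit filtering (see :mod:`exonweaver.hits`), margin
trimming with exhaustive realignment around every block junction,
insertion-versus-intron classification of unmatched target, gap closing with
the spliced aligner, exact pattern search for terminal exons, enforced
absorption of few remaining terminal residues, and splice-site
classification.

Junction handling deliberately separates a *rule* from the *optimiser*: a
stretch of extra target between abutting blocks that is shorter than the
minimum intron length, a multiple of three and free of in-frame stops is
joined into the surrounding exon outright (it is an insertion, and the
penalty scheme alone would rather fabricate a longer intron than pay one gap
penalty per extra codon).  Everything else within the exhaustive-search size
limits goes through the spliced aligner with up to ``max_move_exon`` residues
cut from each flanking block, so low-homology intron borders can be
re-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .align import align_spliced
from .hits import SeedHit, compute_stats
from .params import SearchParams
from .parse import Category, Parse
from .penalties import PenaltyScheme
from .structure import (
    Exon,
    GeneStructure,
    Intron,
    INTRON_DOUBTFUL,
    INTRON_OK,
)
from .translate import STOP, translate_cds, translate_codon


# ---------------------------------------------------------------------------
# intermediate elements


@dataclass
class ExonPart:
    """A run of mapped codons (plus extra codons / frameshift nucleotides)."""

    tstart: int
    tend: int
    qstart: int
    qend: int
    mismatch_q: List[int] = field(default_factory=list)
    stop_q: List[int] = field(default_factory=list)
    fs_t: List[int] = field(default_factory=list)
    extra_codons: int = 0

    @property
    def mapped(self) -> int:
        return self.qend - self.qstart

    @property
    def matched(self) -> int:
        return self.mapped - len(self.mismatch_q)


# element tuples: ("exon", ExonPart) | ("intron", ts, te, phase) | ("qgap", qs, qe)


# ---------------------------------------------------------------------------
# rule functions


def classify_unmatched_target(
    region: str, scheme: PenaltyScheme, table_id: int = 1
) -> str:
    """Classify extra target sequence between blocks with no unmatched query.

    ``merge_into_exon`` when the region is shorter than the minimum intron
    length, a multiple of three, and its in-frame translation is stop-free;
    ``intron_candidate`` otherwise.
    """
    if (
        len(region) < scheme.min_intron_len
        and len(region) % 3 == 0
        and STOP not in translate_cds(region, table_id)
    ):
        return "merge_into_exon"
    return "intron_candidate"


def classify_intron(donor: str, acceptor: str, scheme: PenaltyScheme) -> str:
    """``intron`` when the splice penalty is within the accepted threshold,
    ``intron?`` otherwise."""
    return INTRON_OK if scheme.is_accepted(donor, acceptor) else INTRON_DOUBTFUL


def find_terminal_exon(
    query_terminus: str,
    target_flank: str,
    gap_to_close: int,
    scheme: PenaltyScheme,
    table_id: int = 1,
    side: str = "N",
) -> Optional[int]:
    """Exact pattern search for a terminal exon in a flanking target region.

    For the N side, ``target_flank`` immediately precedes the known gene
    start; a candidate placement at offset ``p`` requires an identically
    translating codon run and an implied intron running to the end of the
    flank, bordered GT/GC---AG and at least the minimum intron length.  The C
    side mirrors this with the flank following the gene end.  Returns the
    offset of the exon within the flank, or None.  Candidates nearest the
    known gene win.
    """
    k = len(query_terminus)
    if k == 0 or k > gap_to_close:
        return None
    n = len(target_flank)
    need = 3 * k
    lmin = scheme.min_intron_len
    if side == "N":
        if n < need + lmin or target_flank[-2:] != "AG":
            return None
        for p in range(n - need - lmin, -1, -1):  # nearest (largest p) first
            if target_flank[p + need : p + need + 2] not in ("GT", "GC"):
                continue
            if translate_cds(target_flank[p : p + need], table_id) == query_terminus:
                return p
        return None
    # C side: implied intron occupies flank[:p], exon at flank[p:p+need]
    if n < need + lmin or target_flank[:2] not in ("GT", "GC"):
        return None
    for p in range(lmin, n - need + 1):  # nearest (smallest p) first
        if target_flank[p - 2 : p] != "AG":
            continue
        if translate_cds(target_flank[p : p + need], table_id) == query_terminus:
            return p
    return None


# ---------------------------------------------------------------------------
# parse conversion


def parse_to_elements(
    parse: Parse, q0: int, t0: int, table_id: int = 1
) -> List[tuple]:
    """Convert an alignment parse into ordered exon/intron/gap elements with
    absolute coordinates."""
    els: List[tuple] = []
    qpos, tpos = q0, t0
    cur: Optional[ExonPart] = None

    def close():
        nonlocal cur
        if cur is not None and (cur.tend > cur.tstart or cur.qend > cur.qstart):
            els.append(("exon", cur))
        cur = None

    def ensure():
        nonlocal cur
        if cur is None:
            cur = ExonPart(tpos, tpos, qpos, qpos)

    for seg in parse.segments:
        cat = seg.category
        if cat is Category.CODON_MATCH:
            ensure()
            aa = translate_codon(seg.target_fragment, table_id)
            if aa != seg.query_fragment:
                cur.mismatch_q.append(qpos)
                if aa == STOP:
                    cur.stop_q.append(qpos)
            qpos += 1
            tpos += 3
            cur.qend, cur.tend = qpos, tpos
        elif cat is Category.GAP:
            ensure()
            tpos += 3
            cur.tend = tpos
            cur.extra_codons += 1
        elif cat is Category.INSERTION:
            close()
            els.append(("qgap", qpos, qpos + 1))
            qpos += 1
        elif cat is Category.FRAMESHIFT:
            ensure()
            cur.fs_t.append(tpos)
            if seg.query_fragment:
                cur.mismatch_q.append(qpos)
                qpos += 1
            tpos += len(seg.target_fragment)
            cur.qend, cur.tend = qpos, tpos
        elif cat is Category.INTRON:
            close()
            ln = len(seg.target_fragment)
            els.append(("intron", tpos, tpos + ln, 0))
            tpos += ln
        elif cat is Category.SPLIT_CODON_INTRON:
            ensure()
            sp = seg.split_position
            om = len(seg.intron_subsequence)
            aa = translate_codon(seg.codon(), table_id)
            if aa != seg.query_fragment:
                cur.mismatch_q.append(qpos)
                if aa == STOP:
                    cur.stop_q.append(qpos)
            qpos += 1
            cur.qend = qpos
            cur.tend = tpos + sp
            close()
            els.append(("intron", tpos + sp, tpos + sp + om, sp))
            tpos += 3 + om
            cur = ExonPart(tpos - (3 - sp), tpos, qpos, qpos)
    close()
    return els


# ---------------------------------------------------------------------------
# the very-short-exon identity rule


def enforce_short_exon_rule(
    elements: List[tuple], target: str, scheme: PenaltyScheme
) -> List[tuple]:
    """Internal exons of 1-4 residues are only kept when they are identical to
    the query and both flanking introns carry accepted splice sites; rejected
    exons are replaced by a single merged intron plus an unmatched query span.
    """
    els = list(elements)
    changed = True
    while changed:
        changed = False
        for k in range(len(els) - 2):
            if not (
                els[k][0] == "intron"
                and els[k + 1][0] == "exon"
                and els[k + 2][0] == "intron"
            ):
                continue
            part: ExonPart = els[k + 1][1]
            aa = part.mapped
            if not 1 <= aa <= 4:
                continue
            il = els[k]
            ir = els[k + 2]
            clean = (
                not part.mismatch_q
                and not part.stop_q
                and not part.fs_t
                and part.extra_codons == 0
            )
            ok_l = scheme.is_accepted(target[il[1] : il[1] + 2], target[il[2] - 2 : il[2]])
            ok_r = scheme.is_accepted(target[ir[1] : ir[1] + 2], target[ir[2] - 2 : ir[2]])
            if clean and ok_l and ok_r:
                continue
            # reject: merge [intron, exon, intron] into one intron + query gap
            p_l, p_r = il[3], ir[3]
            gap_qs, gap_qe = part.qstart, part.qend
            new_ts = il[1] - p_l
            new_te = ir[2] + ((3 - p_r) % 3)
            if p_l > 0:
                # the residue split by the left intron loses its codon too
                prev = els[k - 1][1] if k > 0 and els[k - 1][0] == "exon" else None
                if prev is not None and prev.qend > prev.qstart:
                    prev.qend -= 1
                    prev.tend -= p_l
                    gap_qs = prev.qend
                    prev.mismatch_q = [q for q in prev.mismatch_q if q < prev.qend]
                    prev.stop_q = [q for q in prev.stop_q if q < prev.qend]
            if p_r > 0:
                nxt = els[k + 3][1] if k + 3 < len(els) and els[k + 3][0] == "exon" else None
                if nxt is not None:
                    nxt.tstart = new_te
            els[k : k + 3] = [
                ("intron", new_ts, new_te, 0),
                ("qgap", gap_qs, gap_qe),
            ]
            changed = True
            break
    return els


# ---------------------------------------------------------------------------
# junction realignment


def close_gap_with_nw(
    query: str,
    target: str,
    qs: int,
    qe: int,
    ts: int,
    te: int,
    params: SearchParams,
) -> List[tuple]:
    """Run the spliced aligner on query[qs:qe] vs target[ts:te] and return the
    elements, with the very-short-exon rule applied."""
    parse = align_spliced(query[qs:qe], target[ts:te], params.scheme, params.transtable)
    els = parse_to_elements(parse, qs, ts, params.transtable)
    return enforce_short_exon_rule(els, target, params.scheme)


def _block_part(block, query: str, target: str, table_id: int) -> ExonPart:
    part = ExonPart(block.tstart, block.tend, block.qstart, block.qend)
    for k in range(block.qend - block.qstart):
        codon = target[block.tstart + 3 * k : block.tstart + 3 * k + 3]
        aa = translate_codon(codon, table_id)
        if aa != query[block.qstart + k]:
            part.mismatch_q.append(block.qstart + k)
            if aa == STOP:
                part.stop_q.append(block.qstart + k)
    return part


def refine_hit(
    hit: SeedHit, query: str, target: str, params: SearchParams
) -> GeneStructure:
    """Turn one seed hit into a gene structure on its processing strand.

    ``target`` must be the processing-strand sequence of the contig (the
    reverse complement for minus-strand hits).
    """
    scheme = params.scheme
    tt = params.transtable
    blocks = list(hit.blocks)
    nb = len(blocks)
    lead = [0] * nb
    tail = [0] * nb
    junctions: List[List[tuple]] = []

    for k in range(nb - 1):
        L, R = blocks[k], blocks[k + 1]
        gq = R.qstart - L.qend
        gt = R.tstart - L.tend
        # a block flanked by junctions on both sides splits its margin
        # budget between them so neither junction is starved
        len_l = L.qend - L.qstart
        len_r = R.qend - R.qstart
        tl = min(params.max_move_exon, (len_l - 1) // 2 if k > 0 else len_l - 1)
        tr = min(
            params.max_move_exon,
            (len_r - 1) // 2 if k + 1 < nb - 1 else len_r - 1,
        )
        tl, tr = max(0, tl), max(0, tr)
        use_nw = gq <= params.exhaust_gap_size and gt <= params.exhaust_align_size
        els: List[tuple]
        if gt == 0 and gq == 0:
            els = []
            tl = tr = 0
        elif gq == 0 and classify_unmatched_target(
            target[L.tend : R.tstart], scheme, tt
        ) == "merge_into_exon":
            part = ExonPart(L.tend, R.tstart, L.qend, L.qend, extra_codons=gt // 3)
            els = [("exon", part)]
            tl = tr = 0
        elif use_nw:
            els = close_gap_with_nw(
                query,
                target,
                L.qend - tl,
                R.qstart + tr,
                L.tend - 3 * tl,
                R.tstart + 3 * tr,
                params,
            )
        else:
            tl = tr = 0
            els = []
            if gq > 0:
                els.append(("qgap", L.qend, R.qstart))
            if gt >= scheme.min_intron_len:
                els.append(("intron", L.tend, R.tstart, 0))
            elif gt > 0:
                extra = ExonPart(L.tend, R.tstart, L.qend, L.qend, extra_codons=gt // 3)
                if gt % 3:
                    extra.fs_t.append(L.tend + 3 * (gt // 3))
                els.append(("exon", extra))
        tail[k] = tl
        lead[k + 1] = tr
        junctions.append(els)

    elements: List[tuple] = []
    for k in range(nb):
        b = blocks[k]
        qs = b.qstart + lead[k]
        qe = b.qend - tail[k]
        trimmed = b.__class__(
            qstart=qs,
            qend=qe,
            tstart=b.tstart + 3 * lead[k],
            tend=b.tend - 3 * tail[k],
        )
        elements.append(("exon", _block_part(trimmed, query, target, tt)))
        if k < nb - 1:
            elements.extend(junctions[k])

    elements = _handle_n_terminus(elements, query, target, params)
    elements = _handle_c_terminus(elements, query, target, params)
    return _finalize(elements, hit, query, target, params)


def _first_exon(elements):
    for el in elements:
        if el[0] == "exon":
            return el[1]
    return None


def _last_exon(elements):
    for el in reversed(elements):
        if el[0] == "exon":
            return el[1]
    return None


def _handle_n_terminus(elements, query, target, params):
    first = _first_exon(elements)
    if first is None:
        return elements
    g = first.qstart
    if g == 0:
        return elements
    scheme, tt = params.scheme, params.transtable
    prepend: List[tuple] = []
    if g <= params.gap_to_close:
        f0 = max(0, first.tstart - params.exhaust_align_size)
        flank = target[f0 : first.tstart]
        p = find_terminal_exon(query[:g], flank, params.gap_to_close, scheme, tt, side="N")
        if p is not None:
            exon = ExonPart(f0 + p, f0 + p + 3 * g, 0, g)
            prepend = [("exon", exon), ("intron", f0 + p + 3 * g, first.tstart, 0)]
        elif first.tstart >= 3 * g:
            absorb = ExonPart(first.tstart - 3 * g, first.tstart, 0, g)
            for k in range(g):
                codon = target[absorb.tstart + 3 * k : absorb.tstart + 3 * k + 3]
                aa = translate_codon(codon, tt)
                if aa != query[k]:
                    absorb.mismatch_q.append(k)
                    if aa == STOP:
                        absorb.stop_q.append(k)
            prepend = [("exon", absorb)]
        else:
            prepend = [("qgap", 0, g)]
    else:
        prepend = [("qgap", 0, g)]
    return prepend + elements


def _handle_c_terminus(elements, query, target, params):
    last = _last_exon(elements)
    if last is None:
        return elements
    g = len(query) - last.qend
    if g == 0:
        return elements
    scheme, tt = params.scheme, params.transtable
    append: List[tuple] = []
    if g <= params.gap_to_close:
        flank = target[last.tend : last.tend + params.exhaust_align_size]
        p = find_terminal_exon(
            query[len(query) - g :], flank, params.gap_to_close, scheme, tt, side="C"
        )
        if p is not None:
            ts = last.tend + p
            exon = ExonPart(ts, ts + 3 * g, len(query) - g, len(query))
            append = [("intron", last.tend, ts, 0), ("exon", exon)]
        elif last.tend + 3 * g <= len(target):
            absorb = ExonPart(last.tend, last.tend + 3 * g, len(query) - g, len(query))
            for k in range(g):
                codon = target[absorb.tstart + 3 * k : absorb.tstart + 3 * k + 3]
                aa = translate_codon(codon, tt)
                qpos = len(query) - g + k
                if aa != query[qpos]:
                    absorb.mismatch_q.append(qpos)
                    if aa == STOP:
                        absorb.stop_q.append(qpos)
            append = [("exon", absorb)]
        else:
            append = [("qgap", len(query) - g, len(query))]
    else:
        append = [("qgap", len(query) - g, len(query))]
    return elements + append


def _finalize(elements, hit, query, target, params) -> GeneStructure:
    scheme = params.scheme
    gs = GeneStructure(
        query_id=hit.query_id,
        target_id=hit.target_id,
        strand=hit.strand,
        target_length=hit.target_length or len(target),
    )
    mapped = 0
    cur: Optional[Exon] = None
    cur_end_t = None
    for el in elements:
        if el[0] == "exon":
            part: ExonPart = el[1]
            mapped += part.mapped
            gs.mismatches.extend(part.mismatch_q)
            gs.stops.extend(part.stop_q)
            gs.frameshifts.extend(part.fs_t)
            if cur is not None and cur_end_t == part.tstart:
                cur.tend = part.tend
                cur.qend = max(cur.qend, part.qend)
            else:
                cur = Exon(part.tstart, part.tend, part.qstart, part.qend)
                gs.exons.append(cur)
            cur_end_t = part.tend
        elif el[0] == "intron":
            _, ts, te, phase = el
            gs.introns.append(
                Intron(
                    tstart=ts,
                    tend=te,
                    phase=phase,
                    donor=target[ts : ts + 2],
                    acceptor=target[te - 2 : te],
                    status=(
                        classify_intron(target[ts : ts + 2], target[te - 2 : te], scheme)
                        if te - ts >= scheme.min_intron_len
                        else INTRON_DOUBTFUL
                    ),
                )
            )
            cur = None
            cur_end_t = None
        elif el[0] == "qgap":
            if el[1] < el[2]:
                if gs.gaps and gs.gaps[-1][1] == el[1]:
                    gs.gaps[-1] = (gs.gaps[-1][0], el[2])
                else:
                    gs.gaps.append((el[1], el[2]))
    gs.mismatches.sort()
    gs.stops.sort()
    gs.frameshifts.sort()
    matches = mapped - len(gs.mismatches)
    gs.stats = compute_stats(matches, len(gs.mismatches), len(query))
    return gs
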