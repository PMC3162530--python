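"""Spliced global alignment of a protein fragment to a genomic fragment.

Dynamic program over ``M[i][j]``: the minimal penalty aligning the first
``i`` target nucleotides to the first ``j`` query residues.  Candidate last
segments are a codon match/mismatch, an unmatched residue (insertion), an
extra codon (gap), a 1-2 nt frameshift with or without a residue, and intron
closures.  To close introns in O(1) per cell, nine auxiliary running minima
are maintained:

* one in-frame matrix ``M0`` holding, per query prefix, the cheapest
  ``M[d][j] + intron base + donor penalty`` over all donor positions ``d``
  whose intron would already be long enough;
* four matrices ``M1[n]`` indexed by the nucleotide *before* an intron that
  splits a codon after its first nucleotide (the match penalty is not yet
  known there, since two codon nucleotides follow the intron);
* four matrices ``M2[n]`` indexed by the hypothesised nucleotide *after* the
  intron for codons split after their second nucleotide (here the match
  penalty is already included).

The donor frontier is ``i - min_intron_len`` for in-frame introns and
``i - min_intron_len - 3`` for split codons.  Ties are broken by preferring
codon match > intron > gap > insertion > frameshift, and among equally cheap
intron placements the leftmost donor wins (running minima are only replaced
on strict improvement while sweeping left to right).
"""

from __future__ import annotations

from math import inf
from typing import Dict, List

from .parse import Category, Parse, SegmentPair
from .penalties import PenaltyScheme, match_penalty
from .translate import translate_codon

_NTS = "ACGT"


def align_spliced(
    query_frag: str,
    target_frag: str,
    scheme: PenaltyScheme,
    table_id: int = 1,
) -> Parse:
    """Optimal spliced alignment covering both fragments entirely."""
    q = query_frag.upper()
    t = target_frag.upper()
    m, n = len(q), len(t)
    lmin = scheme.min_intron_len
    pint = scheme.intron_base_penalty
    pins = scheme.insertion_penalty
    pgap = scheme.gap_penalty
    pfs = scheme.frameshift_penalty
    pmm = scheme.mismatch_penalty
    donor = scheme.donor
    acceptor = scheme.acceptor

    # Cache residue comparisons: mism[j-1][codon] computed lazily.
    def mp(res: str, codon: str) -> float:
        return 0.0 if translate_codon(codon, table_id) == res else pmm

    M: List[List[float]] = [[inf] * (m + 1) for _ in range(n + 1)]
    BP: List[List[tuple]] = [[None] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0

    v0 = [inf] * (m + 1)
    a0 = [-1] * (m + 1)
    v1: Dict[str, List[float]] = {c: [inf] * (m + 1) for c in _NTS}
    a1: Dict[str, List[int]] = {c: [-1] * (m + 1) for c in _NTS}
    v2: Dict[str, List[float]] = {c: [inf] * (m + 1) for c in _NTS}
    a2: Dict[str, List[int]] = {c: [-1] * (m + 1) for c in _NTS}

    for i in range(n + 1):
        if i >= 1:
            # admit the newest in-frame donor (frontier i - lmin)
            d = i - lmin
            if d >= 0:
                open_pen = pint + donor(t[d : d + 2])
                row = M[d]
                for j in range(m + 1):
                    cand = row[j] + open_pen
                    if cand < v0[j]:
                        v0[j] = cand
                        a0[j] = d
            # admit the newest split-codon segment start (frontier i - lmin - 3)
            a = i - lmin - 3
            if a >= 0:
                row = M[a]
                n1 = t[a]
                if n1 in v1:
                    open1 = pint + donor(t[a + 1 : a + 3])
                    vrow, arow = v1[n1], a1[n1]
                    for j in range(m + 1):
                        cand = row[j] + open1
                        if cand < vrow[j]:
                            vrow[j] = cand
                            arow[j] = a
                open2 = pint + donor(t[a + 2 : a + 4])
                first2 = t[a : a + 2]
                for c in _NTS:
                    vrow, arow = v2[c], a2[c]
                    for j in range(1, m + 1):
                        cand = row[j - 1] + open2 + mp(q[j - 1], first2 + c)
                        if cand < vrow[j]:
                            vrow[j] = cand
                            arow[j] = a
        Mi = M[i]
        BPi = BP[i]
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = inf
            bp = None
            if i >= 3 and j >= 1:
                cand = M[i - 3][j - 1] + mp(q[j - 1], t[i - 3 : i])
                if cand < best:
                    best, bp = cand, ("codon",)
            if v0[j] < inf:
                cand = v0[j] + acceptor(t[i - 2 : i])
                if cand < best:
                    best, bp = cand, ("intron0", a0[j])
            if j >= 1:
                acc1 = None
                for c in _NTS:
                    base = v1[c][j - 1]
                    if base < inf:
                        if acc1 is None:
                            acc1 = acceptor(t[i - 4 : i - 2])
                        cand = base + acc1 + mp(q[j - 1], c + t[i - 2 : i])
                        if cand < best:
                            best, bp = cand, ("intron1", a1[c][j - 1])
                if i >= 1:
                    c3 = t[i - 1]
                    if c3 in v2 and v2[c3][j] < inf:
                        cand = v2[c3][j] + acceptor(t[i - 3 : i - 1])
                        if cand < best:
                            best, bp = cand, ("intron2", a2[c3][j])
            if i >= 3:
                cand = M[i - 3][j] + pgap
                if cand < best:
                    best, bp = cand, ("gap",)
            if j >= 1:
                cand = Mi[j - 1] + pins
                if cand < best:
                    best, bp = cand, ("ins",)
            for d_ in (2, 1):
                if i >= d_:
                    if j >= 1:
                        cand = M[i - d_][j - 1] + pfs
                        if cand < best:
                            best, bp = cand, ("fsq", d_)
                    cand = M[i - d_][j] + pfs
                    if cand < best:
                        best, bp = cand, ("fs", d_)
            Mi[j] = best
            BPi[j] = bp

    return _traceback(q, t, M, BP)


def _traceback(q: str, t: str, M, BP) -> Parse:
    segs: List[SegmentPair] = []
    i, j = len(t), len(q)
    while i > 0 or j > 0:
        move = BP[i][j]
        kind = move[0]
        if kind == "codon":
            segs.append(SegmentPair(Category.CODON_MATCH, q[j - 1], t[i - 3 : i]))
            i, j = i - 3, j - 1
        elif kind == "gap":
            segs.append(SegmentPair(Category.GAP, "", t[i - 3 : i]))
            i -= 3
        elif kind == "ins":
            segs.append(SegmentPair(Category.INSERTION, q[j - 1], ""))
            j -= 1
        elif kind == "fsq":
            d = move[1]
            segs.append(SegmentPair(Category.FRAMESHIFT, q[j - 1], t[i - d : i]))
            i, j = i - d, j - 1
        elif kind == "fs":
            d = move[1]
            segs.append(SegmentPair(Category.FRAMESHIFT, "", t[i - d : i]))
            i -= d
        elif kind == "intron0":
            d = move[1]
            segs.append(SegmentPair(Category.INTRON, "", t[d:i]))
            i = d
        elif kind == "intron1":
            a = move[1]
            segs.append(
                SegmentPair(
                    Category.SPLIT_CODON_INTRON,
                    q[j - 1],
                    t[a:i],
                    intron_subsequence=t[a + 1 : i - 2],
                    split_position=1,
                )
            )
            i, j = a, j - 1
        elif kind == "intron2":
            a = move[1]
            segs.append(
                SegmentPair(
                    Category.SPLIT_CODON_INTRON,
                    q[j - 1],
                    t[a:i],
                    intron_subsequence=t[a + 2 : i - 1],
                    split_position=2,
                )
            )
            i, j = a, j - 1
        else:  # pragma: no cover - unreachable by construction
            raise RuntimeError("corrupt traceback")
    segs.reverse()
    return Parse(tuple(segs), M[len(t)][len(q)])
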