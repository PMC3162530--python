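"""Reference minimiser over all valid parses, by direct enumeration.

This is deliberately naive: at every position it tries every admissible last
segment, iterating over all intron lengths and both split-codon frames, with
memoisation on the (target, query) prefix lengths.  It shares no machinery
with the production dynamic program (which replaces the per-donor iteration
with running-minimum intron state matrices), so it serves as an independent
check of global optimality on small instances.
"""

from __future__ import annotations

from .errors import InputError
from .penalties import PenaltyScheme, match_penalty

#: Hard size limits; the enumeration is only meant for tiny oracle instances.
MAX_QUERY = 4
MAX_TARGET = 60


def enumerate_parses(
    query_frag: str,
    target_frag: str,
    scheme: PenaltyScheme,
    table_id: int = 1,
) -> float:
    """Exact minimal parse cost for tiny inputs (|query| <= 4, |target| <= 60)."""
    q = query_frag.upper()
    t = target_frag.upper()
    if len(q) > MAX_QUERY or len(t) > MAX_TARGET:
        raise InputError(
            f"enumeration limited to query<={MAX_QUERY} aa and target<={MAX_TARGET} nt"
        )
    lmin = scheme.min_intron_len
    pins = scheme.insertion_penalty
    pgap = scheme.gap_penalty
    pfs = scheme.frameshift_penalty
    memo: dict = {}

    def best(i: int, j: int) -> float:
        # minimal cost aligning t[:i] with q[:j]
        if i == 0 and j == 0:
            return 0.0
        key = (i, j)
        if key in memo:
            return memo[key]
        memo[key] = float("inf")  # guard against accidental cycles
        cands = []
        if i >= 3 and j >= 1:
            cands.append(best(i - 3, j - 1) + match_penalty(q[j - 1], t[i - 3 : i], scheme, table_id))
        if j >= 1:
            cands.append(best(i, j - 1) + pins)
        if i >= 3:
            cands.append(best(i - 3, j) + pgap)
        for d in (1, 2):
            if i >= d:
                cands.append(best(i - d, j) + pfs)
                if j >= 1:
                    cands.append(best(i - d, j - 1) + pfs)
        # plain introns: every admissible length
        for ell in range(lmin, i + 1):
            pen = scheme.intron_penalty(t[i - ell : i])
            if pen is not None:
                cands.append(best(i - ell, j) + pen)
        # split-codon introns ending at i, both frames
        if j >= 1:
            for ell in range(lmin, i - 2):
                # frame 1: codon = t[a] | omega | t[i-2:i], segment spans [a, i)
                a = i - ell - 3
                if a >= 0:
                    omega = t[a + 1 : i - 2]
                    pen = scheme.intron_penalty(omega)
                    if pen is not None:
                        codon = t[a] + t[i - 2 : i]
                        cands.append(
                            best(a, j - 1) + pen + match_penalty(q[j - 1], codon, scheme, table_id)
                        )
                    # frame 2: codon = t[a:a+2] | omega | t[i-1]
                    omega2 = t[a + 2 : i - 1]
                    pen2 = scheme.intron_penalty(omega2)
                    if pen2 is not None:
                        codon2 = t[a : a + 2] + t[i - 1]
                        cands.append(
                            best(a, j - 1) + pen2 + match_penalty(q[j - 1], codon2, scheme, table_id)
                        )
        memo[key] = min(cands) if cands else float("inf")
        return memo[key]

    return best(len(t), len(q))
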