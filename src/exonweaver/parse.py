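"""Alignment parses: ordered segment pairs with per-category penalties.

A *parse* decomposes a (protein, DNA) pair into segment pairs whose query
fragments concatenate to the protein and whose target fragments concatenate to
the DNA.  Each segment falls into one of six categories with a defined
penalty; any other shape is invalid.  The cost of a parse is the penalty sum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence, Tuple

from .errors import InvalidParseError
from .penalties import PenaltyScheme, match_penalty


class Category(enum.Enum):
    CODON_MATCH = "codon_match"
    INSERTION = "insertion"
    GAP = "gap"
    FRAMESHIFT = "frameshift"
    INTRON = "intron"
    SPLIT_CODON_INTRON = "split_codon_intron"


@dataclass(frozen=True)
class SegmentPair:
    """One scored pair (s_k, t_k); split-codon introns also carry the intron
    subsequence and the number of codon nucleotides preceding it (1 or 2)."""

    category: Category
    query_fragment: str
    target_fragment: str
    intron_subsequence: str = ""
    split_position: int = 0

    def codon(self) -> str:
        """The codon read by this segment (split-codon introns reassemble it)."""
        if self.category is Category.SPLIT_CODON_INTRON:
            sp = self.split_position
            return self.target_fragment[:sp] + self.target_fragment[sp + len(self.intron_subsequence):]
        return self.target_fragment


def segment_penalty(seg: SegmentPair, scheme: PenaltyScheme, table_id: int = 1) -> float:
    """Penalty of a single segment; raises InvalidParseError on shape violations."""
    s, t = seg.query_fragment, seg.target_fragment
    cat = seg.category
    if cat is Category.CODON_MATCH:
        if len(s) == 1 and len(t) == 3:
            return match_penalty(s, t, scheme, table_id)
    elif cat is Category.INSERTION:
        if len(s) == 1 and len(t) == 0:
            return scheme.insertion_penalty
    elif cat is Category.GAP:
        if len(s) == 0 and len(t) == 3:
            return scheme.gap_penalty
    elif cat is Category.FRAMESHIFT:
        if len(t) in (1, 2) and len(s) in (0, 1):
            return scheme.frameshift_penalty
    elif cat is Category.INTRON:
        if len(s) == 0:
            pen = scheme.intron_penalty(t)
            if pen is not None:
                return pen
    elif cat is Category.SPLIT_CODON_INTRON:
        omega, sp = seg.intron_subsequence, seg.split_position
        if (
            len(s) == 1
            and sp in (1, 2)
            and len(omega) >= scheme.min_intron_len
            and len(t) == 3 + len(omega)
            and t[sp : sp + len(omega)] == omega
        ):
            pen = scheme.intron_penalty(omega)
            if pen is not None:
                return pen + match_penalty(s, seg.codon(), scheme, table_id)
    raise InvalidParseError(f"segment violates its category invariant: {seg}")


@dataclass(frozen=True)
class Parse:
    """An ordered segment list together with its cost under the active scheme."""

    segments: Tuple[SegmentPair, ...]
    cost: float

    @property
    def query(self) -> str:
        return "".join(s.query_fragment for s in self.segments)

    @property
    def target(self) -> str:
        return "".join(s.target_fragment for s in self.segments)


def parse_cost(
    segments: Sequence[SegmentPair], scheme: PenaltyScheme, table_id: int = 1
) -> float:
    """Sum of segment penalties; raises InvalidParseError if any segment is invalid."""
    return sum(segment_penalty(seg, scheme, table_id) for seg in segments)


def make_parse(
    segments: Sequence[SegmentPair], scheme: PenaltyScheme, table_id: int = 1
) -> Parse:
    return Parse(tuple(segments), parse_cost(segments, scheme, table_id))
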