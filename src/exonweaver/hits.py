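"""Seed hits and per-hit statistics.

A :class:`SeedHit` is a collinear chain of ungapped blocks mapping query
residues to target codons on one contig and strand — the unit the refinement
pipeline turns into a gene structure.  Coordinates are 0-based half-open; for
minus-strand hits, target coordinates refer to the reverse-complemented
contig (the processing strand), and are converted back when results are
written.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

from .errors import InputError


@dataclass(frozen=True)
class Block:
    """One ungapped run: query residues [qstart, qend) against target
    nucleotides [tstart, tend), with tend - tstart == 3 * (qend - qstart)."""

    qstart: int
    qend: int
    tstart: int
    tend: int
    matches: int = 0
    mismatches: int = 0

    def __post_init__(self):
        if not (0 <= self.qstart < self.qend and 0 <= self.tstart < self.tend):
            raise InputError(f"degenerate block: {self}")
        if self.tend - self.tstart != 3 * (self.qend - self.qstart):
            raise InputError(f"block spans are not 1 aa : 3 nt: {self}")


@dataclass(frozen=True)
class SeedHit:
    query_id: str
    target_id: str
    strand: str  # "+" or "-"
    blocks: tuple  # of Block, strictly increasing in both coordinates
    target_length: int = 0

    def __post_init__(self):
        prev = None
        for b in self.blocks:
            if prev is not None and (b.qstart < prev.qend or b.tstart < prev.tend):
                raise InputError("blocks must be strictly increasing in both coordinates")
            prev = b

    @property
    def qstart(self) -> int:
        return self.blocks[0].qstart

    @property
    def qend(self) -> int:
        return self.blocks[-1].qend

    @property
    def matches(self) -> int:
        return sum(b.matches for b in self.blocks)

    @property
    def mismatches(self) -> int:
        return sum(b.mismatches for b in self.blocks)


@dataclass(frozen=True)
class HitStats:
    matches: int
    mismatches: int
    score: float
    identity: float
    coverage: float


def compute_stats(matches: int, mismatches: int, query_length: int) -> HitStats:
    """Coverage = mapped residues (match or mismatch) / query length; identity is
    the matched fraction of mapped residues; score = (matches - mismatches) /
    query length, clipped at zero so junk hits never outrank an empty result."""
    if query_length <= 0:
        raise InputError("query_length must be positive")
    mapped = matches + mismatches
    return HitStats(
        matches=matches,
        mismatches=mismatches,
        score=max(0.0, (matches - mismatches) / query_length),
        identity=(matches / mapped) if mapped else 0.0,
        coverage=mapped / query_length,
    )


def hit_stats(hit: SeedHit, query_length: int) -> HitStats:
    return compute_stats(hit.matches, hit.mismatches, query_length)


def rescore_hit(hit: SeedHit, query: str, target: str, table_id: int = 1) -> SeedHit:
    """Recount per-block matches/mismatches directly from the sequences."""
    from .translate import translate_codon

    new_blocks = []
    for b in hit.blocks:
        matches = 0
        for k in range(b.qend - b.qstart):
            codon = target[b.tstart + 3 * k : b.tstart + 3 * k + 3]
            if translate_codon(codon, table_id) == query[b.qstart + k]:
                matches += 1
        new_blocks.append(
            replace(b, matches=matches, mismatches=(b.qend - b.qstart) - matches)
        )
    return replace(hit, blocks=tuple(new_blocks))


def filter_hits(
    hits: Sequence[SeedHit],
    query_length: int,
    min_score: float = 0.3,
    min_identity: float = 0.9,
    max_mismatch: Optional[int] = None,
    min_coverage: float = 0.6,
) -> List[SeedHit]:
    """Retain exactly the hits meeting all thresholds (coverage strictly below
    ``min_coverage`` is rejected; the boundary value is retained)."""
    kept = []
    for hit in hits:
        st = hit_stats(hit, query_length)
        if st.score < min_score:
            continue
        if st.identity < min_identity:
            continue
        if max_mismatch is not None and st.mismatches > max_mismatch:
            continue
        if st.coverage < min_coverage:
            continue
        kept.append(hit)
    return kept
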