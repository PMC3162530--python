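"""Gene structure results.

All coordinates are 0-based half-open on the *processing strand*: for a
minus-strand result they index the reverse-complemented contig.  Writers
convert to forward-strand / 1-based conventions as each format requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .hits import HitStats

INTRON_OK = "intron"
INTRON_DOUBTFUL = "intron?"


@dataclass
class Exon:
    tstart: int
    tend: int
    qstart: int
    qend: int

    @property
    def aa_len(self) -> int:
        return self.qend - self.qstart


@dataclass
class Intron:
    tstart: int
    tend: int
    phase: int  # codon nucleotides preceding the intron: 0, 1 or 2
    donor: str
    acceptor: str
    status: str  # INTRON_OK or INTRON_DOUBTFUL

    @property
    def length(self) -> int:
        return self.tend - self.tstart


@dataclass
class GeneStructure:
    """Ordered exons and introns of one reconstructed (partial) gene on one
    contig, with unmatched query spans and per-position quality flags."""

    query_id: str
    target_id: str
    strand: str
    target_length: int
    exons: List[Exon] = field(default_factory=list)
    introns: List[Intron] = field(default_factory=list)
    gaps: List[Tuple[int, int]] = field(default_factory=list)  # query aa spans
    mismatches: List[int] = field(default_factory=list)  # query positions
    frameshifts: List[int] = field(default_factory=list)  # target positions
    stops: List[int] = field(default_factory=list)  # query positions
    stats: Optional[HitStats] = None

    @property
    def qstart(self) -> int:
        return self.exons[0].qstart

    @property
    def qend(self) -> int:
        return self.exons[-1].qend

    @property
    def tstart(self) -> int:
        return self.exons[0].tstart

    @property
    def tend(self) -> int:
        return self.exons[-1].tend

    @property
    def genomic_span(self) -> int:
        return self.tend - self.tstart


@dataclass
class GeneResult:
    """A final result: one gene, possibly composed of partial structures on
    several contigs, with combined statistics."""

    query_id: str
    parts: List[GeneStructure]
    stats: HitStats
    joins: List[int] = field(default_factory=list)  # implied inter-contig intron sizes
    dna_coverage: float = 0.0  # percent: 100 * 3*mapped / total genomic span

    @property
    def targets_used(self) -> List[str]:
        return [p.target_id for p in self.parts]

    @property
    def gaps(self) -> List[Tuple[int, int]]:
        out = []
        for p in self.parts:
            out.extend(p.gaps)
        return sorted(out)
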