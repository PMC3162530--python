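"""Search parameters and their documented defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigurationError
from .penalties import PenaltyScheme


@dataclass
class SearchParams:
    """All tunable search parameters.

    Fractions (`min_score`, `min_identity`, `min_coverage`) are expressed in
    [0, 1]; `min_dna_coverage` is a percentage (query/target length ratio of a
    composed hit).  `max_mismatch` of None means unlimited.
    """

    min_score: float = 0.3
    min_identity: float = 0.9
    max_mismatch: Optional[int] = None
    min_coverage: float = 0.6
    transtable: int = 1
    gap_to_close: int = 6
    exhaust_align_size: int = 15000
    exhaust_gap_size: int = 21
    max_move_exon: int = 6
    single_target_hits: bool = False
    multiple_results: bool = False
    max_assemble_size: int = 75000
    min_dna_coverage: float = 0.0
    tilesize: int = 7
    scheme: PenaltyScheme = field(default_factory=PenaltyScheme)

    def __post_init__(self):
        for name in ("min_score", "min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "gap_to_close",
            "exhaust_align_size",
            "exhaust_gap_size",
            "max_move_exon",
            "max_assemble_size",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.tilesize < 3:
            raise ConfigurationError("tilesize must be at least 3")

    @property
    def min_intron_len(self) -> int:
        return self.scheme.min_intron_len

    @property
    def accepted_intron_penalty(self) -> float:
        return self.scheme.accepted_intron_penalty
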