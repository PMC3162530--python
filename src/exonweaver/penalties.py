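"""Penalty model for the spliced protein-to-DNA alignment.

Every alignment segment (codon match, insertion, gap, frameshift, intron,
split-codon intron) carries a non-negative penalty; an optimal alignment
minimises the penalty sum.  Intron penalties decompose into a constant base
penalty plus donor/acceptor splice-site terms that are zero for the canonical
GT---AG pattern, small for the tolerated GC---AG, and larger otherwise.  The
``accepted_intron_penalty`` threshold on the splice terms separates introns
reported as ``intron`` from doubtful ones reported as ``intron?``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

from .errors import ConfigurationError
from .translate import translate_codon

#: Splice penalty applied to donor/acceptor dinucleotides absent from the tables.
NONCANONICAL_SPLICE_PENALTY = 1.0

DEFAULT_DONOR_PENALTY: Mapping[str, float] = MappingProxyType(
    {"GT": 0.0, "GC": 0.25, "AT": 0.75}
)
DEFAULT_ACCEPTOR_PENALTY: Mapping[str, float] = MappingProxyType(
    {"AG": 0.0, "AC": 0.75}
)


@dataclass(frozen=True)
class PenaltyScheme:
    """All penalty constants and splice-site penalty tables.

    Defaults follow the balance that keeps the exhaustive search from
    fabricating artificial short exons: a mismatch is cheaper than any
    structural event, an intron (2.0) is cheaper than two insertions, and a
    frameshift is the most expensive single event.
    """

    mismatch_penalty: float = 1.0
    insertion_penalty: float = 1.5
    gap_penalty: float = 1.1
    frameshift_penalty: float = 2.5
    intron_base_penalty: float = 2.0
    donor_penalty: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_PENALTY)
    )
    acceptor_penalty: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACCEPTOR_PENALTY)
    )
    min_intron_len: int = 22
    accepted_intron_penalty: float = 0.25

    def __post_init__(self):
        for name in (
            "mismatch_penalty",
            "insertion_penalty",
            "gap_penalty",
            "frameshift_penalty",
            "intron_base_penalty",
            "accepted_intron_penalty",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if any(v < 0 for v in self.donor_penalty.values()) or any(
            v < 0 for v in self.acceptor_penalty.values()
        ):
            raise ConfigurationError("splice-site penalties must be non-negative")
        if self.donor_penalty.get("GT", 1.0) != 0.0:
            raise ConfigurationError("donor GT must carry zero penalty")
        if self.acceptor_penalty.get("AG", 1.0) != 0.0:
            raise ConfigurationError("acceptor AG must carry zero penalty")
        # A length-2 intron is the shortest for which donor and acceptor
        # dinucleotides exist at all.
        if self.min_intron_len < 2:
            raise ConfigurationError("min_intron_len must be at least 2")
        object.__setattr__(self, "donor_penalty", MappingProxyType(dict(self.donor_penalty)))
        object.__setattr__(
            self, "acceptor_penalty", MappingProxyType(dict(self.acceptor_penalty))
        )

    # -- splice-site terms -------------------------------------------------

    def donor(self, dinuc: str) -> float:
        return self.donor_penalty.get(dinuc.upper(), NONCANONICAL_SPLICE_PENALTY)

    def acceptor(self, dinuc: str) -> float:
        return self.acceptor_penalty.get(dinuc.upper(), NONCANONICAL_SPLICE_PENALTY)

    def splice_penalty(self, donor: str, acceptor: str) -> float:
        return self.donor(donor) + self.acceptor(acceptor)

    def is_accepted(self, donor: str, acceptor: str) -> bool:
        """True when the border dinucleotides qualify as a clean intron."""
        return self.splice_penalty(donor, acceptor) <= self.accepted_intron_penalty

    # -- segment penalties -------------------------------------------------

    def intron_penalty(self, intron_seq: str) -> Optional[float]:
        """Penalty of an intron candidate, or None when it is shorter than allowed."""
        if len(intron_seq) < self.min_intron_len:
            return None
        return self.intron_base_penalty + self.splice_penalty(
            intron_seq[:2], intron_seq[-2:]
        )

    def with_updates(self, **kwargs) -> "PenaltyScheme":
        from dataclasses import replace

        return replace(self, **kwargs)


def match_penalty(
    residue: str, codon: str, scheme: PenaltyScheme, table_id: int = 1
) -> float:
    """0 when the codon translates to the residue, the mismatch penalty otherwise.

    Stop codons and ambiguous (N-containing) codons score as mismatches; the
    caller is responsible for flagging in-frame stops in its report.
    """
    return 0.0 if translate_codon(codon, table_id) == residue.upper() else scheme.mismatch_penalty


def intron_penalty(intron_seq: str, scheme: PenaltyScheme) -> Optional[float]:
    """Module-level convenience mirroring :meth:`PenaltyScheme.intron_penalty`."""
    return scheme.intron_penalty(intron_seq)
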