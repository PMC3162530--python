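"""Codon translation under NCBI genetic-code tables.

Single-codon translation is the primitive the aligner scores with, so it is
kept separate from Biopython's whole-sequence ``translate``:  codons carrying
assembly ``N`` runs must yield a sentinel rather than raise, and stop codons
are reported explicitly so downstream stages can flag in-frame stops.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

from .errors import ConfigurationError

#: Sentinel returned for stop codons.
STOP = "*"
#: Sentinel returned for codons containing ambiguous nucleotides (N etc.).
UNKNOWN = "X"

_DNA = frozenset("ACGT")


@lru_cache(maxsize=None)
def _codon_map(table_id: int) -> dict:
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise ConfigurationError(f"unsupported translation table: {table_id!r}")
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    return mapping


def supported_tables() -> tuple:
    return tuple(sorted(CodonTable.unambiguous_dna_by_id))


def translate_codon(codon: str, table_id: int = 1) -> str:
    """Translate one codon; ``*`` for stops, ``X`` for ambiguous codons.

    Raises :class:`ConfigurationError` for an unknown ``table_id``.
    """
    mapping = _codon_map(table_id)
    codon = codon.upper()
    if len(codon) != 3 or not _DNA.issuperset(codon):
        return UNKNOWN
    return mapping[codon]


def translate_cds(seq: str, table_id: int = 1) -> str:
    """Translate a nucleotide string codon-by-codon, dropping a trailing partial codon."""
    mapping = _codon_map(table_id)
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(mapping[codon] if _DNA.issuperset(codon) else UNKNOWN)
    return "".join(out)


@lru_cache(maxsize=None)
def codons_for(residue: str, table_id: int = 1) -> tuple:
    """All codons translating to ``residue`` (used when spelling synthetic genes)."""
    mapping = _codon_map(table_id)
    return tuple(sorted(c for c, aa in mapping.items() if aa == residue))


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
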