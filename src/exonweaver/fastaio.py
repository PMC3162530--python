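"""FASTA reading/writing (thin wrappers over Biopython's SeqIO)."""

from __future__ import annotations

from typing import List, Sequence, Tuple

from Bio import SeqIO

from .errors import InputError


def read_fasta(path: str) -> List[Tuple[str, str]]:
    """Ordered (id, uppercase sequence) records; Ns are preserved.

    Raises :class:`InputError` for empty files or when the first
    non-blank line is not a FASTA header.
    """
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise InputError(
                        f"{path}:{lineno}: expected a FASTA header line starting with '>'"
                    )
                break
        else:
            raise InputError(f"{path}: empty FASTA file")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[Tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
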