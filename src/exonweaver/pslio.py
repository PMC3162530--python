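"""PSL (v3, 21 columns) ingestion for externally produced seed alignments.

The expected dialect is protein-query-versus-translated-DNA: block sizes are
in query residues and each block spans three times as many target
nucleotides.  For minus-strand records the target starts are, per the PSL
convention, coordinates on the reverse-complemented target — which is
exactly the processing strand the pipeline uses, so they are kept as is.
"""

from __future__ import annotations

from typing import List

from .errors import InputError
from .hits import Block, SeedHit

_N_COLUMNS = 21


def _is_data_line(fields: List[str]) -> bool:
    return len(fields) > 0 and fields[0].lstrip("-").isdigit()


def read_psl(path: str) -> List[SeedHit]:
    """Parse a PSL file (with or without the 5-line header) into seed hits."""
    hits: List[SeedHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if not _is_data_line(fields):
                continue  # header lines
            if len(fields) != _N_COLUMNS:
                raise InputError(
                    f"{path}:{lineno}: expected {_N_COLUMNS} PSL columns, got {len(fields)}"
                )
            strand = fields[8][-1]
            if strand not in "+-":
                raise InputError(f"{path}:{lineno}: bad strand field {fields[8]!r}")
            qname = fields[9]
            tname = fields[13]
            tsize = int(fields[14])
            block_count = int(fields[17])
            sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
            qstarts = [int(x) for x in fields[19].rstrip(",").split(",")]
            tstarts = [int(x) for x in fields[20].rstrip(",").split(",")]
            if not len(sizes) == len(qstarts) == len(tstarts) == block_count:
                raise InputError(f"{path}:{lineno}: block lists disagree with blockCount")
            blocks = tuple(
                Block(
                    qstart=qs,
                    qend=qs + sz,
                    tstart=ts,
                    tend=ts + 3 * sz,
                    matches=sz,  # provisional; the driver rescores from sequence
                    mismatches=0,
                )
                for sz, qs, ts in zip(sizes, qstarts, tstarts)
            )
            hits.append(
                SeedHit(
                    query_id=qname,
                    target_id=tname,
                    strand=strand,
                    blocks=blocks,
                    target_length=tsize,
                )
            )
    return hits


def forward_span(start: int, end: int, strand: str, target_length: int):
    """Map a processing-strand span to forward-strand coordinates."""
    if strand == "+":
        return start, end
    return target_length - end, target_length - start
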