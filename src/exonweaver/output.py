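"""Result writers: YAML documents and GFF3.

Both writers are deterministic and describe identical coordinates.  YAML
uses the package's internal convention (0-based half-open, forward strand);
GFF3 uses 1-based inclusive coordinates with the CDS phase column derived
from intron phases.
"""

from __future__ import annotations

from typing import IO, List, Sequence

import yaml

from .pslio import forward_span
from .structure import GeneResult, GeneStructure


def _round(x: float) -> float:
    return round(float(x), 6)


def _part_matchings(part: GeneStructure) -> List[dict]:
    feats = []
    for e in part.exons:
        fs, fe = forward_span(e.tstart, e.tend, part.strand, part.target_length)
        feats.append(
            {
                "type": "exon",
                "nucl_start": fs,
                "nucl_end": fe,
                "prot_start": e.qstart,
                "prot_end": e.qend,
            }
        )
    for i in part.introns:
        fs, fe = forward_span(i.tstart, i.tend, part.strand, part.target_length)
        feats.append(
            {
                "type": i.status,  # "intron" or "intron?"
                "nucl_start": fs,
                "nucl_end": fe,
                "phase": i.phase,
                "donor": i.donor,
                "acceptor": i.acceptor,
                "_order": i.tstart,
            }
        )
    # order along the gene (processing-strand coordinates)
    order = {id(f): f.pop("_order", None) for f in feats}
    feats.sort(
        key=lambda f: order[id(f)]
        if order[id(f)] is not None
        else _proc_start(f, part)
    )
    out = []
    gaps = list(part.gaps)
    for f in feats:
        while gaps and f.get("prot_start") is not None and gaps[0][1] <= f["prot_start"]:
            qs, qe = gaps.pop(0)
            out.append({"type": "gap", "prot_start": qs, "prot_end": qe})
        out.append(f)
    for qs, qe in gaps:
        out.append({"type": "gap", "prot_start": qs, "prot_end": qe})
    return out


def _proc_start(feat: dict, part: GeneStructure) -> int:
    fs, fe = feat["nucl_start"], feat["nucl_end"]
    if part.strand == "+":
        return fs
    return part.target_length - fe


def result_to_dict(result: GeneResult) -> dict:
    doc = {
        "query": result.query_id,
        "score": _round(result.stats.score),
        "identity": _round(result.stats.identity),
        "coverage": _round(result.stats.coverage),
        "matches": result.stats.matches,
        "mismatches": result.stats.mismatches,
        "dna_coverage": _round(result.dna_coverage),
        "targets": list(result.targets_used),
        "joins": list(result.joins),
        "parts": [],
    }
    for part in result.parts:
        doc["parts"].append(
            {
                "target": part.target_id,
                "strand": part.strand,
                "matchings": _part_matchings(part),
                "mismatches": list(part.mismatches),
                "frameshifts": [
                    t if part.strand == "+" else part.target_length - t
                    for t in part.frameshifts
                ],
                "stops": list(part.stops),
            }
        )
    return doc


def write_result_yaml(results: Sequence[GeneResult], stream: IO) -> None:
    docs = [result_to_dict(r) for r in results]
    yaml.safe_dump(docs, stream, sort_keys=False, default_flow_style=False)


def write_gff(results: Sequence[GeneResult], stream: IO, source: str = "exonweaver") -> None:
    stream.write("##gff-version 3\n")
    for n, result in enumerate(results, start=1):
        for k, part in enumerate(result.parts, start=1):
            gid = f"{result.query_id}.g{n}.{k}"
            fs, fe = forward_span(part.tstart, part.tend, part.strand, part.target_length)
            score = f"{result.stats.score:.4f}"
            attrs = f"ID=gene:{gid};Name={result.query_id}"
            stream.write(
                "\t".join(
                    [part.target_id, source, "gene", str(fs + 1), str(fe), score,
                     part.strand, ".", attrs]
                )
                + "\n"
            )
            stream.write(
                "\t".join(
                    [part.target_id, source, "mRNA", str(fs + 1), str(fe), score,
                     part.strand, ".", f"ID=mRNA:{gid};Parent=gene:{gid}"]
                )
                + "\n"
            )
            cds = []
            for idx, e in enumerate(part.exons):
                efs, efe = forward_span(e.tstart, e.tend, part.strand, part.target_length)
                if idx == 0:
                    gff_phase = 0
                else:
                    p = part.introns[idx - 1].phase if idx - 1 < len(part.introns) else 0
                    gff_phase = (3 - p) % 3
                cds.append((efs, efe, gff_phase))
            if part.strand == "-":
                cds.sort(key=lambda c: -c[0])
            for efs, efe, gff_phase in cds:
                stream.write(
                    "\t".join(
                        [part.target_id, source, "CDS", str(efs + 1), str(efe), score,
                         part.strand, str(gff_phase), f"Parent=mRNA:{gid}"]
                    )
                    + "\n"
                )
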