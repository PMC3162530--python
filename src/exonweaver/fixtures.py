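"""Synthetic genomes with known gene structures.

The generator emulates the situations the pipeline must master without any
external data: multi-exon genes with introns of chosen lengths, border
dinucleotides and phases (including split codons), micro-exons, divergent
cross-species homologs, in-frame insertions, deletions, sequencing errors
(frameshifts, in-frame stops) and genes spread across contig breaks.

Generation is deterministic per seed.  By default the generator verifies,
with the spliced aligner itself, that every intron-containing region between
two well-anchored exons has a *unique* optimal alignment equal to the truth,
resampling intron interiors otherwise; border recovery is only a well-posed
test on fixtures without equally-scoring decoy splice placements.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .align import align_spliced
from .errors import InputError
from .hits import compute_stats
from .penalties import PenaltyScheme
from .pipeline import classify_intron, parse_to_elements
from .structure import Exon, GeneStructure, Intron, INTRON_DOUBTFUL, INTRON_OK
from .translate import codons_for, revcomp, translate_codon

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: exons at least this long are treated as reliably seedable anchors
ANCHOR_AA = 8
_CTX = 6  # anchor residues included in uniqueness-validation regions


@dataclass
class GeneFixture:
    """A synthetic genome, its query protein, and the ground-truth structure."""

    query_id: str
    protein: str
    contigs: List[Tuple[str, str]]
    parts: List[GeneStructure]  # ground truth, one per contig carrying exons
    seed: int
    joins: List[int] = field(default_factory=list)
    substitutions: List[int] = field(default_factory=list)  # query positions
    notes: Dict[str, object] = field(default_factory=dict)

    @property
    def truth(self) -> GeneStructure:
        if len(self.parts) != 1:
            raise InputError("fixture truth spans several contigs; use .parts")
        return self.parts[0]


# ---------------------------------------------------------------------------
# construction internals


class _GeneModel:
    """Mutable piecewise model: flanks, per-residue codons, introns."""

    def __init__(self, protein, codons, cut_points, introns, flank5, flank3):
        self.protein = protein
        self.codons = codons  # list of 3-nt strings
        self.cut_points = cut_points  # CDS nt offsets of intron insertions
        self.introns = introns  # list of nt strings, parallel to cut_points
        self.flank5 = flank5
        self.flank3 = flank3

    def genome(self) -> str:
        cds = "".join(self.codons)
        pieces = [self.flank5]
        prev = 0
        for cut, intron in zip(self.cut_points, self.introns):
            pieces.append(cds[prev:cut])
            pieces.append(intron)
            prev = cut
        pieces.append(cds[prev:])
        pieces.append(self.flank3)
        return "".join(pieces)

    def truth_elements(self, scheme: PenaltyScheme):
        """Exons and introns in genome coordinates."""
        cds = "".join(self.codons)
        exons: List[Exon] = []
        introns: List[Intron] = []
        gpos = len(self.flank5)
        prev = 0
        bounds = list(zip(self.cut_points, self.introns)) + [(len(cds), None)]
        for cut, intron in bounds:
            seg_len = cut - prev
            qstart = -(-prev // 3)  # first codon starting at/after prev
            qend = -(-cut // 3)  # codons starting before cut
            exons.append(Exon(gpos, gpos + seg_len, qstart, qend))
            gpos += seg_len
            if intron is not None:
                phase = cut % 3
                donor, acceptor = intron[:2], intron[-2:]
                introns.append(
                    Intron(
                        gpos,
                        gpos + len(intron),
                        phase,
                        donor,
                        acceptor,
                        classify_intron(donor, acceptor, scheme),
                    )
                )
                gpos += len(intron)
            prev = cut
        return exons, introns


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_AA) for _ in range(length))


def _spell(rng: random.Random, protein: str, table_id: int) -> List[str]:
    return [rng.choice(codons_for(aa, table_id)) for aa in protein]


def _random_nt(rng: random.Random, length: int, gc: float = 0.5) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(_NT, weights=w, k=length))


def _make_intron(
    rng: random.Random, length: int, donor: str, acceptor: str, gc: float
) -> str:
    if length < 4:
        raise InputError("intron length must be at least 4 to carry both borders")
    return donor + _random_nt(rng, length - 4, gc) + acceptor


def _validate_regions(
    model: _GeneModel,
    scheme: PenaltyScheme,
    table_id: int,
) -> List[Tuple[int, int]]:
    """Indices of introns inside regions whose optimal local alignment does
    not reproduce the truth (ambiguous borders), grouped per region."""
    genome = model.genome()
    exons, introns = model.truth_elements(scheme)
    protein = model.protein
    bad: List[Tuple[int, int]] = []
    # group consecutive non-anchor material between anchor exons
    anchor = [e.aa_len >= ANCHOR_AA for e in exons]
    i = 0
    while i < len(exons) - 1:
        if not anchor[i]:
            i += 1
            continue
        j = i + 1
        while j < len(exons) and not anchor[j]:
            j += 1
        if j >= len(exons):
            break
        # region spans introns i..j-1 and exons i+1..j-1
        A, B = exons[i], exons[j]
        p_l = introns[i].phase
        p_r = introns[j - 1].phase if j - 1 < len(introns) else 0
        ctx_l = min(_CTX, A.aa_len - (1 if p_l > 0 else 0))
        ctx_r = min(_CTX, B.aa_len)
        qa = A.qend - ctx_l
        qb = B.qstart + ctx_r
        ta = A.tend - (p_l if p_l > 0 else 0) - 3 * (ctx_l - (1 if p_l > 0 else 0))
        tb = B.tstart + ((3 - p_r) % 3) + 3 * ctx_r
        parse = align_spliced(protein[qa:qb], genome[ta:tb], scheme, table_id)
        els = parse_to_elements(parse, qa, ta, table_id)
        found = [(e[1], e[2], e[3]) for e in els if e[0] == "intron"]
        want = [(it.tstart, it.tend, it.phase) for it in introns[i:j]]
        clean = all(
            not (e[1].mismatch_q or e[1].stop_q or e[1].fs_t or e[1].extra_codons)
            for e in els
            if e[0] == "exon"
        ) and not any(e[0] == "qgap" for e in els)
        if found != want or not clean:
            bad.append((i, j))
        i = j
    return bad


def generate_gene(
    seed: int,
    protein: Optional[str] = None,
    protein_length: int = 120,
    n_introns: int = 2,
    intron_length_range: Tuple[int, int] = (60, 200),
    border_patterns: Sequence[Tuple[str, str]] = (("GT", "AG"),),
    phases: Optional[Sequence[int]] = None,
    exon_lengths: Optional[Sequence[int]] = None,
    flank_length: Tuple[int, int] = (300, 300),
    gc: float = 0.45,
    table_id: int = 1,
    scheme: Optional[PenaltyScheme] = None,
    ensure_unique_borders: bool = True,
    query_id: str = "query1",
    contig_id: str = "contig1",
) -> GeneFixture:
    """Build a single-contig gene fixture with fully known structure.

    ``exon_lengths`` assigns residues to exons by the codon-start convention
    (a residue whose codon is split by an intron belongs to the upstream
    exon); phases give the number of codon nucleotides preceding each intron.
    """
    rng = random.Random(seed)
    scheme = scheme or PenaltyScheme()
    if protein is None:
        protein = _random_protein(rng, protein_length)
    protein = protein.upper()
    L = len(protein)
    if phases is None:
        phases = [rng.choice((0, 1, 2)) for _ in range(n_introns)]
    phases = list(phases)
    if len(phases) != n_introns:
        raise InputError("need one phase per intron")
    if exon_lengths is None:
        # random partition into n_introns + 1 parts of at least 2 residues
        if L < 2 * (n_introns + 1):
            raise InputError("protein too short for the requested intron count")
        cuts = sorted(rng.sample(range(2, L - 1), n_introns)) if n_introns else []
        exon_lengths = [b - a for a, b in zip([0] + cuts, cuts + [L])]
    exon_lengths = list(exon_lengths)
    if sum(exon_lengths) != L or len(exon_lengths) != n_introns + 1:
        raise InputError("exon lengths must partition the protein")
    # CDS cut points from exon lengths and phases
    cut_points = []
    acc = 0
    for e_len, phase in zip(exon_lengths[:-1], phases):
        acc += e_len
        cut = 3 * (acc - (1 if phase > 0 else 0)) + phase
        cut_points.append(cut)
    if any(not 0 < c < 3 * L for c in cut_points) or sorted(set(cut_points)) != cut_points:
        raise InputError("inconsistent exon lengths / phases")
    codons = _spell(rng, protein, table_id)
    introns = []
    for k in range(n_introns):
        donor, acceptor = border_patterns[k % len(border_patterns)]
        length = rng.randint(*intron_length_range)
        introns.append(_make_intron(rng, length, donor, acceptor, gc))
    model = _GeneModel(
        protein,
        codons,
        cut_points,
        introns,
        _random_nt(rng, flank_length[0], gc),
        _random_nt(rng, flank_length[1], gc),
    )
    if ensure_unique_borders and n_introns:
        for attempt in range(60):
            bad = _validate_regions(model, scheme, table_id)
            if not bad:
                break
            for i, j in bad:
                for k in range(i, j):
                    donor, acceptor = border_patterns[k % len(border_patterns)]
                    length = len(model.introns[k])
                    model.introns[k] = _make_intron(rng, length, donor, acceptor, gc)
        else:
            raise RuntimeError(
                "could not build a fixture with unambiguous intron borders; "
                "try another seed"
            )
    genome = model.genome()
    exons, introns_t = model.truth_elements(scheme)
    truth = GeneStructure(
        query_id=query_id,
        target_id=contig_id,
        strand="+",
        target_length=len(genome),
        exons=exons,
        introns=introns_t,
        stats=compute_stats(L, 0, L),
    )
    fix = GeneFixture(
        query_id=query_id,
        protein=protein,
        contigs=[(contig_id, genome)],
        parts=[truth],
        seed=seed,
    )
    fix.notes["model"] = model
    return fix


# ---------------------------------------------------------------------------
# divergence / error / fragmentation transforms


def apply_divergence(
    fixture: GeneFixture,
    aa_substitution_rate: float = 0.0,
    insertions: Optional[Sequence[dict]] = None,
    deletions: Optional[Sequence[dict]] = None,
    seed: int = 0,
    table_id: int = 1,
) -> GeneFixture:
    """Substitute genome codons (and optionally insert/delete sequence) to
    emulate a cross-species target; the query protein stays fixed and the
    truth is updated with the expected mismatches, merged-exon extensions,
    new introns and gaps."""
    if len(fixture.contigs) != 1:
        raise InputError("apply divergence before fragmenting")
    rng = random.Random(seed)
    contig_id, genome = fixture.contigs[0]
    g = list(genome)
    truth = fixture.parts[0]
    scheme = PenaltyScheme()
    subs: List[int] = []
    split_residues = set()
    for it, ex in zip(truth.introns, truth.exons):
        if it.phase > 0:
            split_residues.add(ex.qend - 1)
    if aa_substitution_rate > 0:
        for ex in truth.exons:
            start_off = (3 - _phase_before(truth, ex)) % 3
            t = ex.tstart + start_off
            q = ex.qstart
            while t + 3 <= ex.tend and q < ex.qend:
                if q not in split_residues and rng.random() < aa_substitution_rate:
                    old = fixture.protein[q]
                    new_aa = rng.choice([a for a in _AA if a != old])
                    g[t : t + 3] = rng.choice(codons_for(new_aa, table_id))
                    subs.append(q)
                t += 3
                q += 1
    new_exons = [replace_exon(e) for e in truth.exons]
    new_introns = [replace_intron(i) for i in truth.introns]
    new_gaps = list(truth.gaps)
    shift_events: List[Tuple[int, int]] = []  # (genome position, shift)

    for spec in insertions or ():
        qpos = spec["after_residue"]
        length = spec.get("length", 9)
        pos = _tpos_of_codon_end(truth, qpos)
        if spec.get("as_intron"):
            donor, acceptor = spec.get("borders", ("GT", "AG"))
            seq = _make_intron(rng, length, donor, acceptor, 0.45)
            new_introns.append(
                Intron(pos, pos + length, 0, donor, acceptor,
                       classify_intron(donor, acceptor, scheme))
            )
            for idx, e in enumerate(new_exons):
                if e.tstart < pos < e.tend:
                    new_exons[idx : idx + 1] = [
                        Exon(e.tstart, pos, e.qstart, qpos + 1),
                        Exon(pos, e.tend, qpos + 1, e.qend),
                    ]
                    break
        else:
            if length % 3 or length >= scheme.min_intron_len:
                raise InputError("a merged insertion must be in-frame and short")
            seq = _stop_free_insert(rng, length, table_id)
        g[pos:pos] = seq
        shift_events.append((pos, length))
    for spec in deletions or ():
        qs = spec["qstart"]
        k = spec["length_aa"]
        pos = _tpos_of_codon_start(truth, qs)
        del g[pos : pos + 3 * k]
        shift_events.append((pos, -3 * k))
        new_gaps.append((qs, qs + k))
        subs = [s for s in subs if not qs <= s < qs + k]

    new_exons, new_introns = _apply_shifts(new_exons, new_introns, shift_events)
    genome2 = "".join(g)
    mapped = len(fixture.protein) - _gap_total(new_gaps)
    part = GeneStructure(
        query_id=truth.query_id,
        target_id=contig_id,
        strand="+",
        target_length=len(genome2),
        exons=new_exons,
        introns=sorted(new_introns, key=lambda i: i.tstart),
        gaps=sorted(new_gaps),
        mismatches=sorted(subs),
        stats=compute_stats(mapped - len(subs), len(subs), len(fixture.protein)),
    )
    # re-derive exon boundaries around merged insertions: an in-frame short
    # insertion leaves the exon intact (it is wider now), handled by shifts
    return GeneFixture(
        query_id=fixture.query_id,
        protein=fixture.protein,
        contigs=[(contig_id, genome2)],
        parts=[part],
        seed=fixture.seed,
        substitutions=sorted(subs),
        notes=dict(fixture.notes),
    )


def replace_exon(e: Exon) -> Exon:
    return Exon(e.tstart, e.tend, e.qstart, e.qend)


def replace_intron(i: Intron) -> Intron:
    return Intron(i.tstart, i.tend, i.phase, i.donor, i.acceptor, i.status)


def _phase_before(truth: GeneStructure, exon: Exon) -> int:
    for it in truth.introns:
        if it.tend == exon.tstart:
            return it.phase
    return 0


def _tpos_of_codon_start(truth: GeneStructure, qpos: int) -> int:
    for ex in truth.exons:
        if ex.qstart <= qpos < ex.qend:
            off = (3 - _phase_before(truth, ex)) % 3
            return ex.tstart + off + 3 * (qpos - ex.qstart)
    raise InputError(f"residue {qpos} not inside any exon")


def _tpos_of_codon_end(truth: GeneStructure, qpos: int) -> int:
    return _tpos_of_codon_start(truth, qpos) + 3


def _stop_free_insert(rng: random.Random, length: int, table_id: int) -> str:
    aas = "".join(rng.choice(_AA) for _ in range(length // 3))
    return "".join(rng.choice(codons_for(a, table_id)) for a in aas)


def _apply_shifts(exons, introns, events):
    for pos, delta in sorted(events, reverse=True):
        for e in exons:
            if e.tstart >= pos:
                e.tstart += delta
            if e.tend > pos:
                e.tend += delta
        for i in introns:
            if i.tstart >= pos and (i.tstart, i.tend) != (pos, pos + delta):
                i.tstart += delta
                i.tend += delta
    return exons, introns


def _gap_total(gaps) -> int:
    return sum(b - a for a, b in gaps)


def inject_errors(
    fixture: GeneFixture,
    n_frameshifts: int = 0,
    n_inframe_stops: int = 0,
    seed: int = 0,
) -> GeneFixture:
    """Plant single-nucleotide deletions (frameshifts) and stop-introducing
    substitutions inside exons; recorded in the truth."""
    if len(fixture.contigs) != 1:
        raise InputError("inject errors before fragmenting")
    rng = random.Random(seed)
    contig_id, genome = fixture.contigs[0]
    g = list(genome)
    truth = fixture.parts[0]
    candidates = []
    split_residues = {ex.qend - 1 for it, ex in zip(truth.introns, truth.exons) if it.phase > 0}
    for ex in truth.exons:
        for q in range(ex.qstart + 1, ex.qend - 1):
            if q not in split_residues and q not in truth.mismatches:
                candidates.append(q)
    rng.shuffle(candidates)
    picked_fs = sorted(candidates[:n_frameshifts])
    picked_stop = sorted(candidates[n_frameshifts : n_frameshifts + n_inframe_stops])
    new_exons = [replace_exon(e) for e in truth.exons]
    new_introns = [replace_intron(i) for i in truth.introns]
    mism = list(truth.mismatches)
    stops: List[int] = list(truth.stops)
    fs_t: List[int] = list(truth.frameshifts)
    events = []
    for q in picked_stop:
        pos = _tpos_of_codon_start(truth, q)
        g[pos : pos + 3] = "TAA"
        stops.append(q)
        mism.append(q)
    for q in picked_fs:
        pos = _tpos_of_codon_start(truth, q)
        del g[pos]  # the codon keeps 2 nt: a frameshift segment
        events.append((pos, -1))
        fs_t.append(pos)
        mism.append(q)
    new_exons, new_introns = _apply_shifts(new_exons, new_introns, events)
    genome2 = "".join(g)
    mapped = len(fixture.protein) - _gap_total(truth.gaps)
    part = GeneStructure(
        query_id=truth.query_id,
        target_id=contig_id,
        strand="+",
        target_length=len(genome2),
        exons=new_exons,
        introns=new_introns,
        gaps=list(truth.gaps),
        mismatches=sorted(mism),
        stops=sorted(stops),
        frameshifts=sorted(fs_t),
        stats=compute_stats(mapped - len(mism), len(mism), len(fixture.protein)),
    )
    return GeneFixture(
        query_id=fixture.query_id,
        protein=fixture.protein,
        contigs=[(contig_id, genome2)],
        parts=[part],
        seed=fixture.seed,
        substitutions=sorted(mism),
        notes=dict(fixture.notes),
    )


def fragment_into_contigs(
    fixture: GeneFixture,
    breakpoints: Sequence[int],
    pads: Optional[Sequence[Tuple[int, int]]] = None,
    seed: int = 0,
) -> GeneFixture:
    """Cut the genome at the given positions (which must not fall inside an
    exon), optionally padding the new contig ends to enlarge the implied
    join, and remap the truth per contig."""
    if len(fixture.contigs) != 1:
        raise InputError("fixture is already fragmented")
    rng = random.Random(seed)
    contig_id, genome = fixture.contigs[0]
    truth = fixture.parts[0]
    breakpoints = sorted(breakpoints)
    for bp in breakpoints:
        if any(e.tstart < bp < e.tend for e in truth.exons):
            raise InputError(f"breakpoint {bp} falls inside an exon")
    pads = list(pads or [(0, 0)] * len(breakpoints))
    pieces: List[str] = []
    bounds = [0] + breakpoints + [len(genome)]
    for k in range(len(bounds) - 1):
        left_pad = _random_nt(rng, pads[k - 1][1]) if k > 0 else ""
        right_pad = _random_nt(rng, pads[k][0]) if k < len(breakpoints) else ""
        pieces.append(left_pad + genome[bounds[k] : bounds[k + 1]] + right_pad)
    contigs = [(f"{contig_id}_part{k+1}", seq) for k, seq in enumerate(pieces)]
    parts: List[GeneStructure] = []
    joins: List[int] = []
    prev_end_gap = None
    for k, (cid, seq) in enumerate(contigs):
        start = bounds[k]
        offset = pads[k - 1][1] if k > 0 else 0  # left padding shifts coordinates
        exs = [
            Exon(e.tstart - start + offset, e.tend - start + offset, e.qstart, e.qend)
            for e in truth.exons
            if e.tstart >= bounds[k] and e.tend <= bounds[k + 1]
        ]
        if not exs:
            continue
        its = [
            Intron(i.tstart - start + offset, i.tend - start + offset, i.phase,
                   i.donor, i.acceptor, i.status)
            for i in truth.introns
            if i.tstart >= bounds[k] and i.tend <= bounds[k + 1]
        ]
        qlo = min(e.qstart for e in exs)
        qhi = max(e.qend for e in exs)
        gaps = [g for g in truth.gaps if qlo <= g[0] and g[1] <= qhi]
        mism = [m for m in truth.mismatches if any(e.qstart <= m < e.qend for e in exs)]
        mapped = sum(e.qend - e.qstart for e in exs) - _gap_total(gaps)
        parts.append(
            GeneStructure(
                query_id=truth.query_id,
                target_id=cid,
                strand="+",
                target_length=len(seq),
                exons=exs,
                introns=its,
                gaps=gaps,
                mismatches=mism,
                stats=compute_stats(mapped - len(mism), len(mism), len(fixture.protein)),
            )
        )
    for a, b in zip(parts, parts[1:]):
        joins.append((a.target_length - a.tend) + b.tstart)
    return GeneFixture(
        query_id=fixture.query_id,
        protein=fixture.protein,
        contigs=contigs,
        parts=parts,
        seed=fixture.seed,
        joins=joins,
        substitutions=list(fixture.substitutions),
        notes=dict(fixture.notes),
    )


def with_paralog(
    fixture: GeneFixture,
    divergence: float = 0.05,
    seed: int = 1,
) -> GeneFixture:
    """Add a second contig carrying a diverged copy of the gene (a paralog),
    for multiple-results behaviour tests."""
    para = apply_divergence(fixture, aa_substitution_rate=divergence, seed=seed)
    pcid = fixture.contigs[0][0] + "_paralog"
    pseq = para.contigs[0][1]
    ppart = para.parts[0]
    ppart.target_id = pcid
    return GeneFixture(
        query_id=fixture.query_id,
        protein=fixture.protein,
        contigs=fixture.contigs + [(pcid, pseq)],
        parts=fixture.parts + [ppart],
        seed=fixture.seed,
        substitutions=list(fixture.substitutions),
        notes=dict(fixture.notes),
    )


def truth_result(fixture: GeneFixture) -> "GeneResult":
    """The fixture truth packaged like a search result (for writers/tests)."""
    from .structure import GeneResult

    parts = fixture.parts
    matches = sum(p.stats.matches for p in parts)
    mism = sum(p.stats.mismatches for p in parts)
    span = sum(p.genomic_span for p in parts) + sum(fixture.joins)
    return GeneResult(
        query_id=fixture.query_id,
        parts=parts,
        stats=compute_stats(matches, mism, len(fixture.protein)),
        joins=list(fixture.joins),
        dna_coverage=(100.0 * 3 * (matches + mism) / span) if span else 0.0,
    )


def write_fixture(fixture: GeneFixture, directory: str) -> Dict[str, str]:
    """Write genome FASTA, protein FASTA and the truth (same YAML schema the
    result writer emits) into ``directory``; returns the paths."""
    import os

    from .fastaio import write_fasta
    from .output import write_result_yaml

    paths = {
        "genome": os.path.join(directory, "genome.fa"),
        "protein": os.path.join(directory, "protein.fa"),
        "truth": os.path.join(directory, "truth.yaml"),
    }
    write_fasta(fixture.contigs, paths["genome"])
    write_fasta([(fixture.query_id, fixture.protein)], paths["protein"])
    with open(paths["truth"], "w") as fh:
        write_result_yaml([truth_result(fixture)], fh)
    return paths


# ---------------------------------------------------------------------------
# the standard evaluation battery


def standard_fixture_set(seed: int, n: int = 25) -> List[GeneFixture]:
    """A deterministic battery of gene fixtures covering 1-12 exons, exon
    sizes from micro (1-4 aa) to 300 aa, intron lengths 22-500 nt, GT---AG
    and GC---AG borders and all three phases.

    Terminal exons are kept at 8+ residues (short terminal exons are a
    documented pattern-search case, exercised separately) and micro-exons are
    internal, mirroring the cases the pipeline is designed around.
    """
    rng = random.Random(seed)
    fixtures: List[GeneFixture] = []
    k = 0
    while len(fixtures) < n:
        n_introns = k % 12
        n_exons = n_introns + 1
        lens: List[int] = []
        micro_at = n_exons // 2 if (n_introns >= 2 and k % 3 == 0) else None
        short_at = (n_exons // 2 + 1) if (n_introns >= 4 and k % 4 == 1) else None
        for i in range(n_exons):
            if i in (0, n_exons - 1):
                lens.append(rng.randint(8, 120) if k % 5 else rng.randint(100, 300))
            elif i == micro_at:
                lens.append(rng.randint(1, 4))
            elif i == short_at:
                lens.append(rng.randint(5, 7))
            else:
                lens.append(rng.randint(8, 60))
        phases = [rng.choice((0, 1, 2)) for _ in range(n_introns)]
        for i, ln in enumerate(lens):
            if ln <= 2:  # ultra-short exons keep codon-aligned borders
                if i - 1 >= 0 and i - 1 < n_introns:
                    phases[i - 1] = 0
                if i < n_introns:
                    phases[i] = 0
        borders = [
            ("GT", "AG") if rng.random() < 0.7 else ("GC", "AG")
            for _ in range(n_introns)
        ]
        sub_seed = rng.randrange(2**31)
        try:
            fixtures.append(
                generate_gene(
                    seed=sub_seed,
                    protein_length=sum(lens),
                    n_introns=n_introns,
                    intron_length_range=(22, 500),
                    border_patterns=borders,
                    phases=phases,
                    exon_lengths=lens,
                    flank_length=(400, 400),
                    query_id=f"query{len(fixtures) + 1}",
                    contig_id=f"contig{len(fixtures) + 1}",
                )
            )
        except RuntimeError:
            pass  # ambiguous-border resampling exhausted; draw a fresh geometry
        k += 1
    return fixtures


# ---------------------------------------------------------------------------
# recovery evaluation (used by tests and the acceptance script)


def evaluate_recovery(results, fixture: GeneFixture) -> Dict[str, object]:
    """Compare the best result against the fixture truth.

    Counts exact exon target spans, exact introns (span + status) and whether
    the whole structure matches exactly, keyed per contig.
    """
    truth_exons = {
        (p.target_id, e.tstart, e.tend) for p in fixture.parts for e in p.exons
    }
    truth_introns = {
        (p.target_id, i.tstart, i.tend, i.status)
        for p in fixture.parts
        for i in p.introns
    }
    found_exons = set()
    found_introns = set()
    if results:
        best = results[0]
        for part in best.parts:
            for e in part.exons:
                found_exons.add((part.target_id, e.tstart, e.tend))
            for i in part.introns:
                found_introns.add((part.target_id, i.tstart, i.tend, i.status))
    exact_e = len(truth_exons & found_exons)
    exact_i = len(truth_introns & found_introns)
    return {
        "exons_total": len(truth_exons),
        "exons_exact": exact_e,
        "introns_total": len(truth_introns),
        "introns_exact": exact_i,
        "structure_exact": truth_exons == found_exons and truth_introns == found_introns,
    }
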