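# exonweaver

Spliced protein-to-genome alignment and exon–intron gene structure
reconstruction.

Given a protein query and eukaryotic genomic DNA, `exonweaver` reconstructs
the gene encoding the protein: exon boundaries, introns with their splice
sites and phases, unmatched query stretches, mismatches, frameshifts and
in-frame stop codons — even when the gene carries micro-exons of a few
residues, diverged exon borders, sequencing errors, or is spread across
several contigs of a fragmented assembly.  It is intended for manual-quality
gene annotation from a known protein (same species or a cross-species
homolog), not for ab-initio prediction.

## The method

Seed hits (from the built-in six-frame translated k-mer search, or from an
external aligner's PSL output) anchor the query on the genome.  Everything
between and around the anchors is resolved by a penalty-scored spliced
Needleman–Wunsch alignment over a protein `s` and a nucleotide fragment `t`.
An alignment is a *parse* Φ = (s₁,t₁)…(s_r,t_r) whose segment pairs are
scored as:

| segment | shape | penalty (default) |
|---|---|---|
| codon match/mismatch | 1 aa : 3 nt | 0 / 1.0 |
| insertion (unmatched residue) | 1 aa : 0 nt | 1.5 |
| gap (extra codon) | 0 aa : 3 nt | 1.1 |
| frameshift | 0–1 aa : 1–2 nt | 2.5 |
| intron | 0 aa : ≥ 22 nt | 2.0 + donor + acceptor |
| split-codon intron | 1 aa : 3 nt + intron | intron penalty + match penalty |

Splice-site terms are zero for GT—AG, small for GC—AG, larger otherwise; an
intron whose donor+acceptor penalty exceeds `accepted_intron_penalty` is
reported as doubtful (`intron?`).  The minimal-cost parse is found by
dynamic programming over `M[i][j]` (minimal cost of aligning the first `i`
nucleotides to the first `j` residues) with nine auxiliary running-minimum
matrices — one for in-frame introns and four each for the two split-codon
phases — so intron closure costs O(1) per cell instead of a scan over all
donor positions.

Around the core aligner, the pipeline filters seed hits (score, identity,
coverage), trims and realigns up to `max_move_exon` residues at every exon
junction, distinguishes short in-frame insertions from true introns
(`min_intron_len`), closes unmatched query gaps of up to
`exhaust_gap_size` residues inside target windows up to
`exhaust_align_size` bp, reconstructs internal 1–4 aa exons only when they
match the query exactly with accepted splice sites, finds short terminal
exons by exact pattern search (up to `gap_to_close` residues), and stitches
partial hits on different contigs into one gene as long as the implied
intron across the contig boundary stays below `max_assemble_size`
(disable cross-contig joins entirely with `--single_target_hits` on
chromosome-scale assemblies).

## Worked example

The synthetic-fixture generator builds genomes with known structures, which
makes a self-contained example:

```python
from exonweaver import generate_gene
from exonweaver.fastaio import write_fasta

fix = generate_gene(seed=42, protein_length=120, n_introns=2,
                    border_patterns=(("GT", "AG"), ("GC", "AG")),
                    phases=(0, 1), intron_length_range=(80, 150))
write_fasta([(fix.query_id, fix.protein)], "query.fa")
write_fasta(fix.contigs, "genome.fa")
```

```bash
exonweaver query.fa genome.fa
```

prints (abridged):

```yaml
- query: query1
  score: 1.0
  identity: 1.0
  coverage: 1.0
  matches: 120
  mismatches: 0
  targets:
  - contig1
  parts:
  - target: contig1
    strand: +
    matchings:
    - {type: exon,   nucl_start: 300, nucl_end: 330, prot_start: 0,  prot_end: 10}
    - {type: intron, nucl_start: 330, nucl_end: 437, phase: 0, donor: GT, acceptor: AG}
    - {type: exon,   nucl_start: 437, nucl_end: 558, prot_start: 10, prot_end: 51}
    - {type: intron, nucl_start: 558, nucl_end: 643, phase: 1, donor: GC, acceptor: AG}
    - {type: exon,   nucl_start: 643, nucl_end: 852, prot_start: 51, prot_end: 120}
```

All 120 residues are mapped (`coverage: 1.0`) without mismatches
(`identity: 1.0`, `score: 1.0`).  The three exons and two introns coincide
exactly with the generator's ground truth, including the phase-1 intron
whose boundary codon is split one nucleotide in (its residue is scored
across the intron).  Coordinates are 0-based half-open on the forward
strand; `--out-format gff` emits the same structure as GFF3 (1-based, with
the CDS phase column derived from the intron phases).

`--help` lists every search parameter with its default; the important ones
are `--min_identity 90`, `--min_coverage 60` (percent), `--min_intron_len
22`, `--gap_to_close 6`, `--exhaust_align_size 15000`, `--exhaust_gap_size
21`, `--max_move_exon 6`, `--max_assemble_size 75000`, `--transtable 1`,
`--accepted_intron_penalty 0.25`, and the flags `--single_target_hits` /
`--chromosome` and `--multiple_results`.  For cross-species searches,
lower `--min_identity`/`--min_coverage`/`--min_score`, reduce `--tilesize`,
and raise `--gap_to_close` (see `docs/methods.md`).

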