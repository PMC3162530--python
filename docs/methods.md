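# Methods

This note records the model implemented by `exonweaver`, the choices made
where the design was genuinely open, and what the synthetic test substrate
does and does not demonstrate.

## The spliced alignment model

A spliced alignment of a protein fragment `s` against a genomic fragment
`t` is a *parse*: an ordered list of segment pairs whose query parts
concatenate to `s` and whose target parts concatenate to `t`.  Six segment
categories are scored (defaults in parentheses): codon match (0) or
mismatch (1.0), unmatched residue / insertion (1.5), extra codon / gap
(1.1), frameshift of one or two nucleotides with or without a residue
(2.5), intron (2.0 plus donor and acceptor splice-site terms), and
split-codon intron — a codon interrupted after its first or second
nucleotide, paying the intron penalty plus the match/mismatch penalty of
the reassembled codon.  The parse cost is the penalty sum; the aligner
returns a global minimum-cost parse.  Any combination of insertions, gaps
and frameshifts can spell out any input pair, so a finite-cost parse always
exists.

The penalty balance matters more than the absolute values: a mismatch is
cheaper than any structural event, so divergent exons align rather than
fragment; an intron (2.0) is cheaper than two unmatched residues (3.0) but
more expensive than one extra codon (1.1), so short in-frame length
differences become exon sequence while long ones become introns; the
frameshift penalty (2.5) exceeds everything else because frameshifts imply
sequencing errors or pseudogenes.

Splice-site terms: donor GT = 0, GC = 0.25, AT = 0.75, others 1.0;
acceptor AG = 0, AC = 0.75, others 1.0.  Only the zero cases carry
biological weight (the canonical and the common tolerated pattern); the
non-zero values are ordering choices.  An intron is reported as `intron` if
donor + acceptor ≤ `accepted_intron_penalty` (default 0.25, admitting
exactly GT—AG and GC—AG) and as doubtful (`intron?`) otherwise; raising the
threshold to ≥ 1.5 admits AT—AC.

`min_intron_len` (default 22 nt) separates introns from insertions.  The
implementation requires it to be at least 2, since shorter "introns" cannot
carry donor and acceptor dinucleotides at all.

## The dynamic program

`M[i][j]` holds the minimal cost of aligning the first `i` target
nucleotides to the first `j` query residues.  Codon, insertion, gap and
frameshift moves look back O(1) cells.  Intron closures would need a scan
over all admissible donor positions; instead nine running minima are
carried per query prefix: one in-frame variant (donor frontier
`i − min_intron_len`) and four per split-codon phase, indexed by the
nucleotide before the intron (phase 1, match penalty not yet computable)
or the hypothesised nucleotide after it (phase 2, match penalty already
included), both with frontier `i − min_intron_len − 3`.  Each variant is
updated in O(1) per cell, giving O(|s|·|t|) time overall.

Ties are broken by a fixed preference order — codon match > intron > gap >
insertion > frameshift — and among equal-cost intron placements the
leftmost donor wins (running minima are replaced only on strict
improvement during the left-to-right sweep).  Output is therefore
deterministic; two runs on identical inputs produce byte-identical YAML
and GFF3.

An independent oracle (`exonweaver.oracle.enumerate_parses`) minimises over
all valid parses by direct enumeration with naive per-donor iteration and
none of the running-minimum machinery; the test suite and the acceptance
script verify exact agreement on hundreds of random instances (queries ≤ 3
aa, targets ≤ 40 nt, reduced minimum intron length so splicing is
reachable at that scale).

Stop codons score as mismatches and are flagged as in-frame stops in the
result rather than forbidden — pseudogenes and sequencing errors must not
abort an alignment.  Codons containing `N` translate to an unknown sentinel
and likewise score as mismatches.  A frameshift segment that carries a
residue pays only the frameshift penalty; its residue is counted as a
mapped mismatch in the statistics so that coverage reflects it.

## Seeding

The built-in seeder indexes exact query k-mers (`tilesize`, default 7) and
scans all six translated frames of every contig.  Seeds are extended
without gaps under X-drop scoring (+1 match, −2 mismatch, drop 6) and
trimmed back to their score maximum.  X-drop was chosen over a
consecutive-mismatch cutoff because isolated chance matches (~5% per
residue) otherwise let extensions creep far into introns — beyond the
six-residue window that junction realignment can repair.  Blocks whose
query or target spans overlap slightly (creep across an exon border, or
across a small indel that shifts the diagonal) are trimmed on the side
whose overlapping residues mismatch, then chained into collinear hits by
weight; several chains per contig allow paralog reporting.

A second, more sensitive pass re-seeds two kinds of regions the primary
pass can miss in diverged targets: windows between two anchored blocks
whose query gap exceeds `exhaust_gap_size` (3-mers, a gentler −1 mismatch
step, minimum five matches per block), and open terminal flanks (3-mers at
the standard strictness — the gentle mode is only safe where both sides
are anchored).  This compensates for the fact that the default
`exhaust_gap_size` of 21 residues presumes the seeding stage finds at
least parts of any longer exon.

Externally produced seed alignments can be supplied as PSL (21 columns,
protein query versus translated DNA, block sizes in residues); minus-strand
records keep the PSL convention of reverse-complement target coordinates,
which is exactly the strand the pipeline processes.

## Hit refinement

Stages, in order: threshold filtering of seed hits (score, identity,
per-hit coverage against the full query length); junction processing;
terminal handling; splice-site classification; statistics.

At each junction between consecutive blocks, up to `max_move_exon`
(default 6) residues are cut from each flanking block — a block with
junctions on both sides splits its budget so neither side is starved, which
matters for exons of around seven residues — and the whole region is
realigned with the exhaustive aligner, provided the query gap is at most
`exhaust_gap_size` and the target span at most `exhaust_align_size`.  This
single mechanism refines low-homology intron borders, places split codons,
closes gaps, and decides insertions versus introns for irreconcilable
regions (lowest-penalty combination of gaps, frameshifts and introns).

One rule is applied *before* the aligner: a junction without unmatched
query whose extra target is shorter than `min_intron_len`, a multiple of
three and stop-free in frame is joined into the surrounding exon outright.
Under the default penalties the optimiser would instead fabricate a longer
intron (2.0 + splice terms plus one displaced residue beats seven extra
codons at 7.7), so the insertion-versus-intron decision is a rule, not an
optimisation.

After realignment, internal exons of 1–4 residues are kept only if they
match the query exactly, contain no frameshifts or extra codons, and both
flanking introns carry accepted splice sites; otherwise the exon is
removed, the two introns merge (split-codon remainders are returned to
their anchors so the merged intron is phase 0), and the residues are
recorded as unmatched.  Note that when the freed residues can be absorbed
at a neighbouring border for a lower total penalty (one intron plus a few
mismatches can undercut two introns plus a gap), the optimal parse never
proposes the micro-exon and the residues surface as flagged border
mismatches instead of a gap — the rule governs what may be *reconstructed
as an exon*, not where rejected residues end up.

Unmatched termini of up to `gap_to_close` (default 6) residues are first
sought as terminal exons by exact pattern search in the flanking target
(identical translation, implied intron of at least `min_intron_len`
bordered GT/GC—AG; the nearest placement wins); failing that, the residues
are absorbed into the first/last exon at the cost of mismatches, so small
terminal divergence does not leave gaps.  The pattern search assumes a
codon-aligned junction; terminal micro-exons behind split codons are a
known limitation.

## Assembly across contigs

Partial gene structures on different contigs are chained in query order
(best-scoring compatible chain by dynamic programming).  Two parts are
compatible if their query spans do not overlap by more than six residues
(small overlaps from chance extension at a contig edge are trimmed from
the side with more mismatches in the overlap window) and the implied
intron — distance from the last exon to the contig end plus the first-exon
offset on the next contig — is at most `max_assemble_size` (default
75,000 nt).  Oversize joins split the composition and only the
best-scoring side is reported unless `multiple_results` is on.
`min_dna_coverage` (percent, default off) additionally bounds the
query/target length ratio of a composition, computed as
100 · 3 · mapped residues / (exon spans + implied joins).
`single_target_hits` disables composition entirely — on chromosome-scale
assemblies a chance match on another chromosome must not be stitched into
the gene.  Codons split by an intron that is itself interrupted by a
contig boundary are not reassembled across the join; the one or two
orphaned nucleotides stay unassigned.

Statistics: identity = matches / (matches + mismatches); coverage =
(matches + mismatches) / query length; score = (matches − mismatches) /
query length, clipped at zero.  The score formula is this package's
definition (chosen to be monotone in hit quality and additive across
composed parts); per-hit coverage uses the full query length, which means
multi-contig searches need a lowered `min_coverage` — a partial hit on a
short contig cannot reach 60% of the whole query by construction.

## The synthetic substrate

`exonweaver.fixtures` generates genomes with fully known structures:
codon-spelled proteins interleaved with introns of requested lengths,
border dinucleotides and phases inside random flanks; transforms apply
amino-acid substitutions (query fixed, genome codons replaced), in-frame
insertions below the intron threshold, longer splice-bordered insertions,
deletions, single-nucleotide frameshifts, stop-codon injections, contig
fragmentation with optional padding, and paralog duplication.  Generation
is deterministic per seed.

Because exact border recovery is only well-posed when the optimum is
unique, the generator verifies each intron-containing region between two
well-anchored exons (≥ 8 residues) against the aligner itself and
resamples intron interiors that admit an equally-scoring alternative
placement.  This uses the aligner as a checker only; its optimality is
established independently by the enumeration oracle.

The standard battery (`standard_fixture_set`) draws 25 genes per seed with
1–12 exons, exon sizes from 1 to 300 residues including internal
micro-exons, intron lengths 22–500 nt, mixed GT—AG / GC—AG borders and all
three phases.  Terminal exons are kept at ≥ 8 residues (seedable); short
terminal exons are exercised by dedicated pattern-search fixtures.  The
divergence battery applies 20% per-residue substitution and runs with the
cross-species settings (`tilesize` 5, `min_identity` 0.6, `min_score` 0.2,
`min_coverage` 0.3, `gap_to_close` 15); the residual exon losses there are
dominated by unlucky substitution clusters (local identity far below 80%)
and by substitution-induced cost ties at borders, both inherent to the
penalty model.  Fragmentation fixtures break phase-0 introns, reflecting
the split-codon limitation above.

What the fixtures do not emulate: realistic splice-site motifs beyond the
border dinucleotides, codon-usage bias, repeats and low-complexity
sequence, assembly N-runs at scale, and genome-scale target sizes.
Passing the batteries therefore demonstrates the correctness of the
reconstruction logic under the model's own assumptions, not sensitivity on
real genomes, where the seeding stage would face repeats and much larger
search spaces.

## Problem sizes

The exhaustive aligner is quadratic, so it is confined to short fragments:
query gaps of at most `exhaust_gap_size` residues and target windows of at
most `exhaust_align_size` bp, plus the trimmed junction margins.  The
acceptance script runs the full pipeline on the 25-gene battery (genomes
of a few kb; a few minutes on one CPU); the oracle comparison uses 500
random instances at the sizes given above.
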