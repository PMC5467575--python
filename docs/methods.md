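# Methods

## Coordinate model

All coordinates are 1-based, fully closed, on both strands of a sequence
region; strand is +1/−1 (a feature with no meaningful strand is stored on
+1 with an attribute). Only the UCSC chain writer converts to 0-based
half-open, and only on output. A coordinate system has a unique rank per
species; exactly one coordinate system per species carries DNA
(`is_sequence_level`), and a region is *toplevel* precisely when it never
appears as a component in the assembly table — the flag is recomputed, not
declared, whenever assembly rows are registered. Annotation is accepted
only on toplevel regions; storing a feature on a component raises an error
advising projection first.

Projection composes pairwise mappings along the shortest path in the graph
of coordinate-system pairs that share assembly rows (breadth-first, ties
broken by coordinate-system id, so multi-hop chromosome → scaffold → contig
paths and direct cross-version edges both resolve deterministically).
Within one hop, a segment's target strand is the product of the slice
strand and the row orientation; source offsets are expressed along the
query slice in its own orientation, which makes hop composition a pure
offset shift. `transform` succeeds only for a single, length-preserving
segment — the in-band failure value is `None`, not an exception, because a
feature spanning a junction is an expected outcome, not a fault.

Sequence retrieval assembles a slice from sequence-level components via
projection, filling unmapped bases with uppercase `N`. Soft masking
lowercases stored repeat features, hard masking replaces them with `N`;
masking is applied on the forward strand before reverse complementing.
Origin-wrapping slices on circular regions are split at the origin and
reassembled (length = region length − start + 1 + end).

## Windowed range queries

Feature rows are indexed by (feature type, region, start). The store keeps,
per (feature type, coordinate system), the maximum length of any feature
ever stored (`meta_coord`); the bound is raised on insert and never
lowered — a stale upper bound only widens the scan, it cannot lose results.
A query over [s, e] scans starts in [max(1, s − m), e] and post-filters
end ≥ s. On circular regions the window is taken modulo the region length
(a second scan of the region tail when s − m < 1), the overlap predicate is
circle-aware, and origin-spanning queries are decomposed into
[start, length] and [1, end] with results deduplicated by internal id —
a feature that itself wraps the origin is returned once. Results are always
ordered by (start, internal id). A type/coordinate-system pair with no
`meta_coord` entry falls back to a full scan of the region.

## Gene models and operons

Transcript exons must share one region and strand (trans-splicing is out of
scope), be non-overlapping, and be listed 5′→3′ along the transcript
strand. Spliced cDNA is the strand-aware concatenation of exon sequences;
the CDS is delimited by (start exon, offset) and (end exon, offset) within
the spliced cDNA, translated with the standard genetic code only (an
alternative codon table would slot into `genes.translate`, but none is
wired up), trailing stop removed, and a CDS length not divisible by three
rejected. Exon phase is stored but not validated against the translation —
the two encodings are conventionally redundant. Gene children load lazily:
fetching a gene touches no transcript or exon rows until `.transcripts` is
accessed, which the store's query counter makes testable.

A polycistronic mRNA is an operon transcript linked to ≥ 1 genes; every
encoded polypeptide is also an ordinary gene/transcript record, so
translation needs no special path. Operons must contain at least one
transcript, and gene links are checked at store time and again at product
listing (a dangling link is an error, not an empty result).

## Assembly exceptions

An exception record substitutes a range of a reference region with a range
of an exception region. The two presentation modes differ deliberately:

* PAR: the exception chromosome (e.g. Y) is real; its PAR ranges store no
  sequence or annotation and are served from the reference (X) range,
  shifted by (exception start − reference start). Ranges must be equal
  length.
* Patch/haplotype: the presented chromosome is virtual — the reference
  chromosome with replaced ranges swapped in. Flanks come from the
  reference (downstream coordinates shift by the cumulative
  exception-minus-reference length difference); the exception span comes
  from the patch's own storage, whose coordinates are already expressed
  relative to the whole virtual chromosome. Flank lengths on both sides of
  each exception must agree, which is checked at view construction.

Boundary-crossing annotation is stored on both sides; cross-boundary
queries merge the piecewise sub-queries and deduplicate, keyed by stable id
when present, else by (type, projected coordinates, strand). Features are
returned unclipped (full extent, possibly outside the queried range).
Alt-allele groups require ≥ 2 members and exactly one nominated reference
copy; provenance flags (manual/automatic, sequencing error/individual
variability) are free combinations of the four defined values.

## Cross-version mapping and chains

Contigs shared between assembly versions pair by versioned accession first,
else by MD5 of the uppercased sequence (ambiguity codes included verbatim),
also testing the reverse complement's MD5, which yields orientation −1. An
MD5 collision between distinct sequences aborts — practically impossible,
but it guards fixture bugs. "Neighbouring" contigs collapse into one
chromosome-level segment only under exact abutment on both assemblies and
overall orientation +1 for every member; a flipped contig never joins a run
even if its neighbours are conserved. Externally aligned segments (7-column
TSV) may fill gaps but must not overlap existing rows on either side.

Chain export groups collinear rows, encodes inter-block gaps as dt/dq,
writes minus-strand query coordinates on the reversed strand per the chain
convention, scores each chain as the sum of its block sizes (liftover
ignores the score) and numbers chains from 1. The test suite maps positions
through an independent chain parser and requires exact agreement with the
direct mapping.

## Stable-identifier mapping

Parameters, with defaults and the reasoning where the choice was open:

| parameter | value | notes |
|---|---|---|
| exon shared-base threshold | 90% | denominator = max of the two exon lengths (symmetric and strict; union or reciprocal overlap were alternatives) |
| cross-assembly identity threshold | 90% | global alignment, match +1 / mismatch −1 / gap −2; identity = matching columns / aligned columns, terminal gaps counted |
| transcript intersection threshold | 25%, inclusive | denominator = max of exon counts |
| biotype penalty | 10% within a broad class, 20% across | applied multiplicatively to the base score; broad classes: coding, small_ncRNA, long_ncRNA, pseudogene; unknown biotypes are their own class |
| ambiguity margin | 0.02 absolute | scores closer than this are "comparable" |

Threshold comparisons are done in integer arithmetic
(100·overlap ≥ 90·length) so the boundary cases 89/90/91 and 24/25 behave
exactly, independent of float rounding.

Matching is greedy, not optimal assignment: candidates are served in
descending score with deterministic tie-breaks (lower internal ids), which
matches the one-pass hierarchical description and makes reruns
byte-identical; optimal bipartite matching is the noted alternative.
Ambiguous sources run a cascade — equal biotype, then more shared mapped
children, then (as a configurable last resort) the lower target internal
id; with the last resort disabled an unresolved tie discards the old id and
mints fresh ones for all contenders.

Versions: an exon keeps its version only on a perfect coordinate-and-
sequence match; a transcript only when both its spliced cDNA and its
ordered exon coordinate list are unchanged (across assemblies, cDNA
equality alone, since coordinates necessarily differ); a translation when
the protein is unchanged; a gene only when the multiset of child
(id, version) pairs is unchanged. Versions never decrease. Exon matching
is globally one-to-one (not per transcript), and penalties apply at
transcript scoring only — neither propagates to gene scoring.

## External references

Method priority for naming is direct > location overlap > checksum >
alignment, then the configured source rank, then accession — resolved per
gene (children's links roll up to the gene), which is one of two defensible
readings of per-gene vs per-source resolution. Only naming-eligible sources
can name a gene; with none, the clone name is used, so naming is total and
deterministic for any input. Alignment links record query identity
(matches / query length × 100), target identity (over target length) and a
CIGAR (M/I/D, I = query insertion); per external accession, hits are capped
to the best-n distinct identity levels (default 1, "top five" style
configurable) above the identity floor, with ties at a kept level all
linked. The winning source's transitive children import as DEPENDENT
links. Ontology evidence codes are stored verbatim, unvalidated.

## Synthetic data

The generator emulates a small multi-chromosome genome: 2 chromosomes of
4–7 contigs (8–15 kb each, 25% chance of a 100–500 b gap between
neighbours), uniform random nucleotides, and up to 40 genes per release
(1–6 exons of 60–240 b, introns 50–400 b, intergenic 200–1500 b, 80%
coding, 30% of eligible coding genes with a second, exon-skipping
transcript). Every draw descends from one seed through stable hashing of a
path string, so adding one fixture never shifts another's randomness, and
identical seeds yield byte-identical outputs.

A release pair applies a fixed edit plan to the second release — small
(+5 b) and large (+len/4) exon extensions, internal exon drops, biotype
switches within and across broad classes, relocations into a reserved
chromosome tail, deletions — and emits a truth table of intended id fates
derived from the edit list and the thresholds above, with release B
relabelled with provisional ids so nothing can pass by inheritance. Large
extensions are restricted to multi-exon genes, because on a single-exon
gene the exon's death cascades into transcript and gene death. split/merge
edits are not generated: their expected fates depend on the ambiguity
resolution itself, so a truth table for them would not be independent of
the mapper under test.

What the generator does not emulate: realistic base composition, repeats,
UTR/CDS structure beyond a trimmed full-cDNA CDS, overlapping genes,
trans-splicing, or assembly errors. Passing tests therefore demonstrate the
correctness of the coordinate arithmetic, query windows, thresholds and
bookkeeping — not robustness to the ambiguities of real annotation, where
overlapping paralogues and fragmented assemblies would exercise the
ambiguity cascade far harder.

Problem sizes in the checks: 1,000 features × 200 slices for the range-
query oracle, 500 slices for the projection oracle, 1,000 positions for
the chain round trip, and threshold sweeps over all 100 integer fractions;
the full suite completes in seconds.

## Known limitations

* Projection assumes each component range is used once per (region, target
  coordinate system); shared components across chromosomes project to all
  placements.
* The embedded store is single-writer; there is no connection pooling or
  schema migration (explicit non-goals).
* Cross-assembly exon comparison aligns all source×target pairs — fine at
  desk scale, quadratic in general; a k-mer prefilter would be the next
  step.
* The alt-allele model allows groups of any size ≥ 2, although curated data
  mostly shows pairs.
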