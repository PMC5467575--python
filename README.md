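# genomekit

An embedded genome-annotation store and mapping toolkit, written for people
who need the machinery behind a genome browser — coordinate systems,
assemblies, gene models, release-to-release identifier continuity — without
running a database server. Everything lives in a single SQLite file (or in
memory) behind a small Python API and a `genomekit` command-line tool.

## What it models

A genome assembly is a hierarchy of **sequence regions** grouped into ranked
**coordinate systems** (chromosome → scaffold → contig). DNA is stored once,
at the sequence level; an `assembly` table of AGP-like rows says how larger
regions are tiled from components. Two operations move annotation between
levels: `project(slice, cs)` reports where each base of a slice lands in a
target coordinate system (a list of mapped segments; gaps are simply
absent), and `transform(feature, cs)` rewrites a feature into target
coordinates when — and only when — the projection is a single contiguous,
length-preserving segment.

On top of that sit:

* **Windowed range queries.** Feature tables are indexed by
  (type, region, start), and the store tracks m, the maximum feature length
  per (type, coordinate system). A query over [s, e] scans starts in
  [s − m, e] and keeps rows with end ≥ s — exactly the overlapping set,
  without a binning scheme. Circular replicons are supported: a query that
  spans the origin is decomposed into two scans and deduplicated, and
  features may wrap the origin once (end < start).
* **Gene models** — gene/transcript/exon/translation graphs with lazy child
  loading, spliced cDNA and standard-code translation, plus polycistronic
  **operons** whose transcripts link several polypeptide-encoding genes.
* **Assembly exceptions** — pseudo-autosomal regions, patches and alternate
  haplotypes stored as substitution records rather than duplicated
  sequence. Exceptions are presented as whole chromosomes; queries across a
  boundary merge the flanking and exception stores and collapse duplicated
  annotation. Alt-allele groups nominate a reference gene copy.
* **Cross-version assembly mapping** — shared contigs are identified by
  versioned accession or MD5 (reverse complement included), conserved runs
  are collapsed into chromosome-level segments, externally aligned segments
  fill the gaps, and the result exports as a UCSC chain file for liftover.
* **Stable-identifier mapping** — hierarchical identity between two
  releases: exon pairs keep their id at ≥ 90% shared bases (same assembly)
  or ≥ 90% alignment identity (across assemblies); transcripts map on exon
  sets with ≥ 25% intersection, penalised 10% for a biotype change within a
  broad functional class and 20% across classes; genes follow shared
  transcripts; versions increment whenever the underlying object changed.
  Ambiguous candidates are resolved by biotype, shared children, then
  internal id — or discarded for fresh ids.
* **External references** — direct, location-overlap, checksum and
  alignment linkage to external accessions, with method-priority naming
  (committee names first, clone names as the last resort) and transitive
  DEPENDENT links.

## Worked example

```python
from genomekit import (Store, CoordSystem, AssemblySegment, Slice, Feature)
from genomekit import assembly, features

store = Store()                       # in-memory; pass a path to persist
store.add_species("example_species")
chrom_cs = store.add_coord_system(CoordSystem("chromosome", version="ASM1", rank=1))
contig_cs = store.add_coord_system(CoordSystem("contig", rank=2,
                                               is_sequence_level=True))
chrom = store.add_seq_region("1", chrom_cs, 100)
a = store.add_seq_region("A", contig_cs, 60, sequence="ACGT" * 15)
b = store.add_seq_region("B", contig_cs, 40, sequence="TTGCA" * 8)
store.register_assembly([AssemblySegment(chrom, 1, 60, a, 1, 60, 1),
                         AssemblySegment(chrom, 61, 100, b, 1, 40, 1)])

for seg in assembly.project(store, Slice(chrom, 55, 65), contig_cs):
    t = seg.target
    print(f"slice bases {seg.src_start}-{seg.src_end} -> "
          f"{t.region.name}:{t.start}-{t.end}:{t.strand:+d}")
print(assembly.fetch_sequence(store, Slice(chrom, 55, 65)))
```

prints

```
slice bases 1-6 -> A:55-60:+1
slice bases 7-11 -> B:1-5:+1
GTACGTTTGCA
```

The slice 1:55–65 straddles the contig junction, so it projects to two
segments — bases 1–6 on contig A and 7–11 on contig B — and its sequence is
stitched from both components. A feature inside one contig transforms
cleanly (`transform` returns it in contig coordinates); one spanning the
junction returns `None`.

The CLI wraps the same library: `genomekit make-fixtures out/ --seed 1`
writes a synthetic release pair (AGP + FASTA + GFF3 + truth table),
`genomekit init` / `load-assembly` / `load-genes` build a store from those
files, `genomekit query store.db "1:55-65"` prints overlapping features as
GFF3, and `genomekit map-ids old.db new.db --out events.tsv` runs the
stable-id pipeline.

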