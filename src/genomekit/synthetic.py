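"""Deterministic synthetic genomes, annotation releases and truth tables.

Everything is driven by a single seed; sub-generators derive child seeds by
stable hashing of a path string, so adding one fixture never shifts the
randomness of another.  Scales are kept desk-sized (chromosomes of tens of
kilobases, tens of genes) so every test runs in seconds.

``make_release_pair`` builds two annotation releases of the same genome
where the second release carries a known perturbation plan (exon
extensions, dropped exons, biotype switches, relocations, deletions) and
emits a truth table of intended stable-id fates derived from the edit list
and the mapping thresholds — the ground truth that the stable-ID pipeline
must recover.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import altloci, features
from .genes import Exon, Gene, Transcript, Translation
from .model import AssemblySegment, CoordSystem, Feature
from .stable_ids import EXON_THRESHOLD_PERCENT
from .store import Store

BASES = np.array(list("ACGT"))


def child_seed(seed: int, *path: str) -> int:
    digest = hashlib.sha256(("/".join(map(str, path)) + f"#{seed}").encode())
    return int.from_bytes(digest.digest()[:4], "big") % (2 ** 31)


def rng_for(seed: int, *path: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *path))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@dataclass
class FixtureSpec:
    seed: int = 1
    species: str = "example_species"
    assembly_version: str = "ASM1"
    n_chromosomes: int = 2
    contigs_per_chromosome: tuple = (4, 7)
    contig_len: tuple = (8000, 15000)
    gap_prob: float = 0.25
    gap_len: tuple = (100, 500)
    n_genes: int = 40
    exons_per_gene: tuple = (1, 6)
    exon_len: tuple = (60, 240)
    intron_len: tuple = (50, 400)
    intergenic: tuple = (200, 1500)
    coding_fraction: float = 0.8
    two_transcript_fraction: float = 0.3
    tail_reserve: int = 9000  # chromosome tail kept free for relocations
    # perturbation plan sizes (release B edits)
    n_extend_small: int = 4
    n_extend_large: int = 2
    n_drop_exon: int = 3
    n_biotype_within: int = 2
    n_biotype_across: int = 2
    n_relocate: int = 2
    n_delete: int = 3
    extend_small_bases: int = 5


# -- genome ----------------------------------------------------------------

def build_genome(store: Store, spec: FixtureSpec) -> None:
    """Chromosomes assembled from contigs with optional inter-contig gaps."""
    store.add_species(spec.species)
    chrom_cs = store.add_coord_system(CoordSystem(
        "chromosome", version=spec.assembly_version, rank=1))
    contig_cs = store.add_coord_system(CoordSystem(
        "contig", rank=2, is_sequence_level=True))
    for c in range(1, spec.n_chromosomes + 1):
        rng = rng_for(spec.seed, "genome", c)
        n_contigs = int(rng.integers(*spec.contigs_per_chromosome,
                                     endpoint=True))
        cursor = 1
        placements = []
        for i in range(1, n_contigs + 1):
            length = int(rng.integers(*spec.contig_len, endpoint=True))
            name = f"CTG{c}_{i}"
            seq = random_dna(rng, length)
            contig = store.add_seq_region(name, contig_cs, length, sequence=seq)
            store.set_region_attrib(contig.internal_id, "accession",
                                    f"{name}.1")
            placements.append((contig, cursor, cursor + length - 1))
            cursor += length
            if rng.random() < spec.gap_prob:
                cursor += int(rng.integers(*spec.gap_len, endpoint=True))
        chrom = store.add_seq_region(str(c), chrom_cs, cursor - 1)
        store.register_assembly([
            AssemblySegment(chrom, s, e, contig, 1, contig.length, 1)
            for contig, s, e in placements])


# -- gene generation -------------------------------------------------------

NONCODING_BIOTYPES = ("snRNA", "scRNA", "lncRNA")


def _make_translation(transcript: Transcript) -> Translation:
    """A translation spanning the whole spliced cDNA, trimmed to a full
    codon count at the 3' end."""
    cdna_len = sum(len(e) for e in transcript.exons)
    trim = cdna_len % 3
    last = transcript.exons[-1]
    return Translation(
        stable_id=transcript.stable_id.replace("GKT", "GKP"),
        start_exon=transcript.exons[0], seq_start=1,
        end_exon=last, seq_end=len(last) - trim)


def generate_genes(store: Store, spec: FixtureSpec) -> list[Gene]:
    """Deterministic gene models laid out along the chromosomes.

    The layout depends only on the spec, so two stores built from the same
    spec get base-identical annotation.
    """
    chrom_cs = store.coord_system("chromosome", spec.assembly_version)
    chroms = sorted(store.regions(chrom_cs), key=lambda r: r.name)
    genes: list[Gene] = []
    counter = 0
    for chrom in chroms:
        rng = rng_for(spec.seed, "genes", chrom.name)
        cursor = int(rng.integers(*spec.intergenic, endpoint=True))
        limit = chrom.length - spec.tail_reserve
        while counter < spec.n_genes:
            n_exons = int(rng.integers(*spec.exons_per_gene, endpoint=True))
            strand = 1 if rng.random() < 0.5 else -1
            coding = rng.random() < spec.coding_fraction
            exon_lens = [int(rng.integers(*spec.exon_len, endpoint=True))
                         for _ in range(n_exons)]
            introns = [int(rng.integers(*spec.intron_len, endpoint=True))
                       for _ in range(n_exons - 1)]
            span = sum(exon_lens) + sum(introns)
            if cursor + span > limit:
                break
            counter += 1
            gid = counter
            spans = []
            pos = cursor
            for i, length in enumerate(exon_lens):
                spans.append((pos, pos + length - 1))
                pos += length + (introns[i] if i < len(introns) else 0)
            exons = [Exon(
                feature=Feature("exon", chrom, s, e, strand,
                                analysis="synthetic",
                                stable_id=f"GKE{gid:05d}_{i+1}", version=1),
                stable_id=f"GKE{gid:05d}_{i+1}", version=1)
                for i, (s, e) in enumerate(spans)]
            if strand == -1:
                exons = exons[::-1]
            biotype = ("protein_coding" if coding else
                       str(rng.choice(NONCODING_BIOTYPES,
                                      p=[0.4, 0.3, 0.3])))
            transcripts = []
            t1 = Transcript(
                feature=Feature("transcript", chrom, cursor,
                                cursor + span - 1, strand,
                                analysis="synthetic",
                                stable_id=f"GKT{gid:05d}_1", version=1),
                stable_id=f"GKT{gid:05d}_1", version=1, biotype=biotype,
                exons=list(exons))
            if coding:
                t1.translation = _make_translation(t1)
            transcripts.append(t1)
            if (coding and n_exons >= 3
                    and rng.random() < spec.two_transcript_fraction):
                kept = [e for i, e in enumerate(exons) if i != 1]
                t2 = Transcript(
                    feature=Feature("transcript", chrom, cursor,
                                    cursor + span - 1, strand,
                                    analysis="synthetic",
                                    stable_id=f"GKT{gid:05d}_2", version=1),
                    stable_id=f"GKT{gid:05d}_2", version=1, biotype=biotype,
                    exons=kept)
                t2.translation = _make_translation(t2)
                t2.translation = replace(
                    t2.translation,
                    stable_id=t2.translation.stable_id + "b")
                transcripts.append(t2)
            genes.append(Gene(
                feature=Feature("gene", chrom, cursor, cursor + span - 1,
                                strand, analysis="synthetic",
                                stable_id=f"GKG{gid:05d}", version=1),
                stable_id=f"GKG{gid:05d}", version=1, biotype=biotype,
                transcripts=transcripts))
            cursor += span + int(rng.integers(*spec.intergenic, endpoint=True))
    return genes


def store_release(store: Store, genes: list[Gene]) -> None:
    from .genes import store_gene
    for gene in genes:
        store_gene(store, gene)


def build_release(spec: FixtureSpec, path: str = ":memory:") -> tuple[Store, list[Gene]]:
    store = Store(path)
    build_genome(store, spec)
    genes = generate_genes(store, spec)
    store_release(store, genes)
    return store, genes


# -- perturbation plan -----------------------------------------------------

@dataclass(frozen=True)
class Edit:
    op: str
    gene: str  # source stable id
    bases: int = 0


@dataclass
class ReleasePair:
    spec: FixtureSpec
    store_a: Store
    store_b: Store
    genes_a: list[Gene]
    genes_b: list[Gene]
    plan: list[Edit]
    truth: list[tuple]  # (object_type, old_id, fate, provisional_new_id)


def default_plan(genes: list[Gene], spec: FixtureSpec) -> list[Edit]:
    rng = rng_for(spec.seed, "plan")
    single_coding = [g for g in genes if g.biotype == "protein_coding"
                     and len(g.transcripts) == 1]
    droppable = [g for g in single_coding if len(g.transcripts[0].exons) >= 3]
    small_nc = [g for g in genes if g.biotype in ("snRNA", "scRNA")]
    plan: list[Edit] = []
    used: set[str] = set()

    def take(pool, n, op, bases=0):
        avail = [g for g in pool if g.stable_id not in used]
        picked = list(rng.choice(len(avail), size=min(n, len(avail)),
                                 replace=False)) if avail else []
        for idx in sorted(int(i) for i in picked):
            g = avail[idx]
            used.add(g.stable_id)
            plan.append(Edit(op, g.stable_id, bases))

    take(single_coding, spec.n_extend_small, "extend_exon",
         spec.extend_small_bases)
    # a large extension kills the exon's id; on a single-exon gene that
    # would cascade into transcript/gene death, so require a second exon
    multi_exon = [g for g in single_coding
                  if len(g.transcripts[0].exons) >= 2]
    take(multi_exon, spec.n_extend_large, "extend_exon_large")
    take(droppable, spec.n_drop_exon, "drop_exon")
    take(small_nc, spec.n_biotype_within, "biotype_within")
    take(single_coding, spec.n_biotype_across, "biotype_across")
    take(genes, spec.n_relocate, "relocate")
    take(genes, spec.n_delete, "delete")
    return plan


def _rightmost_exon(t: Transcript) -> Exon:
    return max(t.exons, key=lambda e: e.feature.end)


def _shift_gene(gene: Gene, delta: int) -> None:
    def shift(f: Feature) -> Feature:
        return replace_feature(f, start=f.start + delta, end=f.end + delta)
    gene.feature = shift(gene.feature)
    moved: dict[str, Exon] = {}
    for t in gene.transcripts:
        t.feature = shift(t.feature)
        new_exons = []
        for e in t.exons:
            if e.stable_id not in moved:
                moved[e.stable_id] = Exon(shift(e.feature), e.stable_id,
                                          e.version, e.phase)
            new_exons.append(moved[e.stable_id])
        t.exons = new_exons
        if t.translation is not None:
            t.translation = Translation(
                t.translation.stable_id,
                moved[t.translation.start_exon.stable_id],
                t.translation.seq_start,
                moved[t.translation.end_exon.stable_id],
                t.translation.seq_end, t.translation.version)


def replace_feature(f: Feature, **kw) -> Feature:
    args = dict(feature_type=f.feature_type, region=f.region, start=f.start,
                end=f.end, strand=f.strand, analysis=f.analysis,
                attributes=dict(f.attributes), stable_id=f.stable_id,
                version=f.version)
    args.update(kw)
    return Feature(**args)


def _refresh_spans(gene: Gene) -> None:
    for t in gene.transcripts:
        lo = min(e.feature.start for e in t.exons)
        hi = max(e.feature.end for e in t.exons)
        t.feature = replace_feature(t.feature, start=lo, end=hi)
    lo = min(t.feature.start for t in gene.transcripts)
    hi = max(t.feature.end for t in gene.transcripts)
    gene.feature = replace_feature(gene.feature, start=lo, end=hi)


def apply_plan(genes_b: list[Gene], plan: list[Edit],
               spec: FixtureSpec) -> list[tuple]:
    """Mutate release-B genes per the plan; relabel every B object with a
    provisional id; return the truth table of intended fates.

    Fates: kept (same id, same version), version_bump (same id, version +1),
    new (fresh id), dead (source id retired).  Truth is derived from the
    edit list plus the retention thresholds, not from running the mapper.
    """
    by_id = {g.stable_id: g for g in genes_b}
    edited: dict[str, str] = {g.stable_id: "untouched" for g in genes_b}
    relocate_cursor: dict[str, int] = {}
    for edit in plan:
        gene = by_id[edit.gene]
        edited[edit.gene] = edit.op
        t = gene.transcripts[0]
        if edit.op in ("extend_exon", "extend_exon_large"):
            exon = _rightmost_exon(t)
            k = edit.bases if edit.op == "extend_exon" else len(exon) // 4
            new_exon = Exon(replace_feature(exon.feature,
                                            end=exon.feature.end + k),
                            exon.stable_id, exon.version, exon.phase)
            t.exons = [new_exon if e.stable_id == exon.stable_id else e
                       for e in t.exons]
            if t.translation is not None:
                t.translation = _make_translation(t)
            _refresh_spans(gene)
        elif edit.op == "drop_exon":
            t.exons = [e for i, e in enumerate(t.exons) if i != 1]
            if t.translation is not None:
                t.translation = _make_translation(t)
            _refresh_spans(gene)
        elif edit.op == "biotype_within":
            new_bt = "scRNA" if gene.biotype == "snRNA" else "snRNA"
            gene.biotype = new_bt
            for tx in gene.transcripts:
                tx.biotype = new_bt
        elif edit.op == "biotype_across":
            gene.biotype = "lncRNA"
            for tx in gene.transcripts:
                tx.biotype = "lncRNA"
                tx.translation = None
        elif edit.op == "relocate":
            chrom = gene.feature.region
            cursor = relocate_cursor.get(
                chrom.name, chrom.length - spec.tail_reserve + 500)
            _shift_gene(gene, cursor - gene.feature.start)
            relocate_cursor[chrom.name] = gene.feature.end + 300
        elif edit.op == "delete":
            genes_b.remove(gene)
        else:
            raise ValueError(f"unknown edit op {edit.op!r}")

    # provisional relabelling + truth derivation
    truth: list[tuple] = []
    counter = {"gene": 0, "transcript": 0, "exon": 0, "translation": 0}

    def prv(kind: str) -> str:
        counter[kind] += 1
        return f"PRV{kind[0].upper()}{counter[kind]:05d}"

    return _relabel_and_derive(genes_b, plan, spec, edited, prv, truth)


def _relabel_and_derive(genes_b, plan, spec, edited, prv, truth):
    """Relabel every B object with a provisional id and derive truth rows."""
    ops = {e.gene: e for e in plan}
    for gene in genes_b:
        op_edit = ops.get(gene.stable_id)
        op = op_edit.op if op_edit else "untouched"
        all_new = op == "relocate"
        gene_old = gene.stable_id
        new_gid = prv("gene")
        gene.stable_id = new_gid
        gene.feature = replace_feature(gene.feature, stable_id=new_gid)
        t_bump = op in ("extend_exon", "extend_exon_large", "drop_exon")
        seen_exons: set[str] = set()
        renamed: dict[str, Exon] = {}
        for t in gene.transcripts:
            t_old = t.stable_id
            new_tid = prv("transcript")
            t.stable_id = new_tid
            t.feature = replace_feature(t.feature, stable_id=new_tid)
            if all_new:
                truth.append(("transcript", t_old, "dead", ""))
                truth.append(("transcript", "", "new", new_tid))
            else:
                truth.append(("transcript", t_old,
                              "version_bump" if t_bump else "kept", new_tid))
            rightmost = _rightmost_exon(t)
            new_exons = []
            for e in t.exons:
                if e.stable_id in renamed:
                    new_exons.append(renamed[e.stable_id])
                    continue
                e_old = e.stable_id
                new_eid = prv("exon")
                ne = Exon(replace_feature(e.feature, stable_id=new_eid),
                          new_eid, e.version, e.phase)
                renamed[e_old] = ne
                new_exons.append(ne)
                if e_old in seen_exons:
                    continue
                seen_exons.add(e_old)
                if all_new:
                    truth.append(("exon", e_old, "dead", ""))
                    truth.append(("exon", "", "new", new_eid))
                elif op in ("extend_exon", "extend_exon_large") \
                        and e is rightmost:
                    new_len = len(ne)
                    k = (op_edit.bases if op == "extend_exon"
                         else (new_len - new_len * 4 // 5))
                    old_len = new_len - (op_edit.bases if op == "extend_exon"
                                         else new_len // 5)
                    kept = 100 * old_len >= EXON_THRESHOLD_PERCENT * new_len
                    if kept:
                        truth.append(("exon", e_old, "version_bump", new_eid))
                    else:
                        truth.append(("exon", e_old, "dead", ""))
                        truth.append(("exon", "", "new", new_eid))
                else:
                    truth.append(("exon", e_old, "kept", new_eid))
            t.exons = new_exons
            if t.translation is not None:
                p_old = t.translation.stable_id
                new_pid = prv("translation")
                t.translation = Translation(
                    new_pid, renamed[t.translation.start_exon.stable_id],
                    t.translation.seq_start,
                    renamed[t.translation.end_exon.stable_id],
                    t.translation.seq_end, t.translation.version)
                if all_new:
                    truth.append(("translation", p_old, "dead", ""))
                    truth.append(("translation", "", "new", new_pid))
                else:
                    truth.append(("translation", p_old,
                                  "version_bump" if t_bump else "kept",
                                  new_pid))
        if all_new:
            truth.append(("gene", gene_old, "dead", ""))
            truth.append(("gene", "", "new", new_gid))
        else:
            truth.append(("gene", gene_old,
                          "version_bump" if t_bump else "kept", new_gid))
    # deletions and dropped children
    deleted = {e.gene for e in plan if e.op == "delete"}
    return truth, deleted


def make_release_pair(spec: Optional[FixtureSpec] = None) -> ReleasePair:
    spec = spec or FixtureSpec()
    store_a, genes_a = build_release(spec)
    store_b = Store()
    build_genome(store_b, spec)
    genes_b = generate_genes(store_b, spec)
    plan = default_plan(genes_a, spec)
    truth, deleted = apply_plan(genes_b, plan, spec)
    # death rows for deleted genes and their children
    by_id = {g.stable_id: g for g in genes_a}
    for gid in sorted(deleted):
        g = by_id[gid]
        truth.append(("gene", gid, "dead", ""))
        seen = set()
        for t in g.transcripts:
            truth.append(("transcript", t.stable_id, "dead", ""))
            if t.translation is not None:
                truth.append(("translation", t.translation.stable_id,
                              "dead", ""))
            for e in t.exons:
                if e.stable_id not in seen:
                    seen.add(e.stable_id)
                    truth.append(("exon", e.stable_id, "dead", ""))
        # drop_exon rows: the dropped exon dies
    for edit in plan:
        if edit.op == "drop_exon":
            g = by_id[edit.gene]
            dropped = g.transcripts[0].exons[1]
            truth.append(("exon", dropped.stable_id, "dead", ""))
        if edit.op == "biotype_across":
            g = by_id[edit.gene]
            for t in g.transcripts:
                if t.translation is not None:
                    truth.append(("translation", t.translation.stable_id,
                                  "dead", ""))
    store_release(store_b, genes_b)
    return ReleasePair(spec, store_a, store_b, genes_a, genes_b, plan, truth)


def write_release(store: Store, genes: list[Gene], outdir, prefix: str,
                  spec: FixtureSpec) -> dict[str, str]:
    """Serialise one release as AGP + contig FASTA + GFF3; returns paths."""
    import os

    from .io import agp as agp_io
    from .io import fasta as fasta_io
    from .io import gff3 as gff3_io

    os.makedirs(outdir, exist_ok=True)
    chrom_cs = store.coord_system("chromosome", spec.assembly_version)
    contig_cs = store.sequence_level_cs()
    paths = {
        "agp": os.path.join(outdir, f"{prefix}.agp"),
        "fasta": os.path.join(outdir, f"{prefix}.contigs.fa"),
        "gff3": os.path.join(outdir, f"{prefix}.gff3"),
    }
    agp_io.write_agp(paths["agp"], store, chrom_cs, contig_cs)
    fasta_io.write_fasta(paths["fasta"], {
        r.name: store.sequence(r) for r in store.regions(contig_cs)})
    gff3_io.write_gff3(paths["gff3"], genes=genes)
    return paths


# -- exception fixtures ----------------------------------------------------

@dataclass
class ExceptionFixture:
    store: Store
    oracle: dict[str, str]          # region name -> literal substituted string
    exceptions: list
    par_region_name: str = "Y"
    patch_region_name: str = "PATCH_1"


def make_exception_fixture(seed: int = 1) -> ExceptionFixture:
    """An X/Y PAR pair plus a length-changing patch, with literal oracles.

    The oracle strings are built by naive substitution so the exception
    machinery can be checked base-for-base against plain concatenation.
    """
    rng = rng_for(seed, "exceptions")
    store = Store()
    store.add_species("example_species")
    chrom_cs = store.add_coord_system(CoordSystem("chromosome", version="ASM1",
                                                  rank=1))
    contig_cs = store.add_coord_system(CoordSystem("contig", rank=2,
                                                   is_sequence_level=True))

    def add_chrom(name, length, pieces):
        chrom = store.add_seq_region(name, chrom_cs, length)
        segs = []
        for (asm_s, asm_e, ctg_name) in pieces:
            seq = random_dna(rng, asm_e - asm_s + 1)
            ctg = store.add_seq_region(ctg_name, contig_cs, len(seq),
                                       sequence=seq)
            segs.append(AssemblySegment(chrom, asm_s, asm_e, ctg, 1,
                                        len(seq), 1))
        store.register_assembly(segs)
        return chrom

    x = add_chrom("X", 5000, [(1, 5000, "CTGX")])
    # Y's own sequence covers only the region between the two PARs
    y = add_chrom("Y", 4000, [(801, 3499, "CTGY")])
    nine = add_chrom("9", 6000, [(1, 6000, "CTG9")])
    patch = add_chrom("PATCH_1", 6075, [(3000, 3475, "CTGP")])

    par1 = altloci.AssemblyException("PAR", y, 1, 800, x, 1, 800)
    par2 = altloci.AssemblyException("PAR", y, 3500, 4000, x, 4300, 4800)
    fix = altloci.AssemblyException("PATCH_FIX", patch, 3000, 3475,
                                    nine, 3000, 3400)
    for exc in (par1, par2, fix):
        altloci.register_exception(store, exc)

    from .assembly import fetch_sequence
    from .model import Slice
    x_seq = fetch_sequence(store, Slice(x, 1, 5000))
    y_own = fetch_sequence(store, Slice(y, 1, 4000))
    nine_seq = fetch_sequence(store, Slice(nine, 1, 6000))
    patch_own = fetch_sequence(store, Slice(patch, 3000, 3475))
    oracle = {
        "Y": x_seq[0:800] + y_own[800:3499] + x_seq[4299:4800],
        "PATCH_1": nine_seq[0:2999] + patch_own + nine_seq[3400:6000],
    }

    def put(ftype, region, s, e, stable_id=None, strand=1):
        features.store_feature(store, Feature(
            ftype, region, s, e, strand, analysis="synthetic",
            stable_id=stable_id, version=1 if stable_id else None))

    put("simple", x, 100, 200, "XPAR1A")       # inside PAR1 (on X)
    put("simple", x, 2000, 2100, "XMID")       # X-only
    put("simple", x, 4400, 4500, "XPAR2A")     # inside PAR2 source range
    put("simple", y, 1000, 1100, "YOWN")       # Y outside the PARs
    put("simple", nine, 500, 600, "N9UP")      # upstream of the patch
    put("simple", nine, 3100, 3150, "N9IN")    # inside the replaced range
    put("simple", nine, 5000, 5100, "N9DOWN")  # downstream (shifts +75)
    # boundary-crossing annotation is stored on both sides
    put("simple", nine, 2900, 3050, "BND1")
    put("simple", patch, 2900, 3050, "BND1")
    put("simple", patch, 3200, 3260, "PNOVEL")  # patch-only novel feature
    return ExceptionFixture(store, oracle, [par1, par2, fix])


# -- circular fixture ------------------------------------------------------

def make_circular_fixture(seed: int = 1, length: int = 1000,
                          n_features: int = 30) -> tuple[Store, "SeqRegion", list[Feature]]:
    """A circular plasmid with random features, some wrapping the origin."""
    rng = rng_for(seed, "circular")
    store = Store()
    store.add_species("example_species")
    cs = store.add_coord_system(CoordSystem("plasmid", rank=1,
                                            is_sequence_level=True))
    region = store.add_seq_region("pMINI", cs, length, circular=True,
                                  sequence=random_dna(rng, length))
    out = []
    for i in range(n_features):
        start = int(rng.integers(1, length, endpoint=True))
        flen = int(rng.integers(20, max(21, length // 4), endpoint=True))
        end = start + flen - 1
        if end > length:
            end -= length  # wraps the origin
        f = Feature("simple", region, start, end,
                    1 if rng.random() < 0.5 else -1, analysis="synthetic")
        features.store_feature(store, f)
        out.append(f)
    return store, region, out


from .model import SeqRegion  # noqa: E402  (typing reference above)
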