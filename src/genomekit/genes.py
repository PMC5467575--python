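"""Gene / transcript / exon / translation objects and polycistronic operons.

Genes fetched from a store load their children on demand: the transcript
(and exon) tables are not touched until ``gene.transcripts`` is accessed,
which is observable through the store's query counter.

A polycistronic mRNA is modelled as an operon transcript linked to several
polypeptide-encoding genes; each encoded polypeptide is nevertheless held as
its own gene/transcript record, so translation needs no special casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from . import assembly
from .model import Feature, ModelError
from .store import Store, StoreError

#: Broad functional classes used when penalising biotype changes during
#: stable-ID mapping.  A change within one class (snRNA -> scRNA) is mild; a
#: change across classes (coding -> non-coding) is severe.
BROAD_CLASSES: dict[str, frozenset] = {
    "coding": frozenset({
        "protein_coding", "IG_C_gene", "IG_V_gene", "TR_C_gene", "TR_V_gene"}),
    "small_ncRNA": frozenset({
        "snRNA", "scRNA", "snoRNA", "miRNA", "tRNA", "rRNA", "misc_RNA"}),
    "long_ncRNA": frozenset({"lncRNA", "lincRNA", "antisense", "sense_intronic"}),
    "pseudogene": frozenset({
        "pseudogene", "processed_pseudogene", "unprocessed_pseudogene"}),
}


def broad_class(biotype: str) -> str:
    for cls, members in BROAD_CLASSES.items():
        if biotype in members:
            return cls
    return biotype  # unknown biotypes are their own class


@dataclass
class Exon:
    feature: Feature
    stable_id: str
    version: int = 1
    phase: int = -1
    internal_id: Optional[int] = None

    def __len__(self):
        return len(self.feature)


@dataclass
class Translation:
    stable_id: str
    start_exon: Exon
    seq_start: int  # 1-based offset of first coding base within start_exon
    end_exon: Exon
    seq_end: int    # 1-based offset of last coding base within end_exon
    version: int = 1
    internal_id: Optional[int] = None


@dataclass
class Transcript:
    feature: Feature
    stable_id: str
    biotype: str = "protein_coding"
    version: int = 1
    exons: list[Exon] = field(default_factory=list)
    translation: Optional[Translation] = None
    internal_id: Optional[int] = None

    def validate(self) -> None:
        if self.version < 1:
            raise ModelError(f"transcript {self.stable_id}: version must be >= 1")
        if not self.exons:
            raise ModelError(f"transcript {self.stable_id} has no exons")
        region_id = self.exons[0].feature.region.internal_id
        strand = self.exons[0].feature.strand
        for e in self.exons:
            if e.feature.region.internal_id != region_id or e.feature.strand != strand:
                raise ModelError(
                    f"transcript {self.stable_id}: exons must share one region "
                    f"and strand (trans-splicing is not modelled)")
        ordered = sorted(self.exons, key=lambda e: e.feature.start,
                         reverse=(strand == -1))
        if [e.stable_id for e in ordered] != [e.stable_id for e in self.exons]:
            raise ModelError(
                f"transcript {self.stable_id}: exons must be listed 5'->3' "
                f"along the transcript strand")
        spans = sorted((e.feature.start, e.feature.end) for e in self.exons)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c <= b:
                raise ModelError(
                    f"transcript {self.stable_id}: exons overlap "
                    f"({a}-{b} vs {c}-{d})")
        if self.translation is not None:
            tr = self.translation
            for exon, off, label in ((tr.start_exon, tr.seq_start, "seq_start"),
                                     (tr.end_exon, tr.seq_end, "seq_end")):
                if exon.stable_id not in {e.stable_id for e in self.exons}:
                    raise ModelError(
                        f"transcript {self.stable_id}: translation exon "
                        f"{exon.stable_id} is not one of its exons")
                if not 1 <= off <= len(exon):
                    raise ModelError(
                        f"transcript {self.stable_id}: {label}={off} outside "
                        f"exon {exon.stable_id} (length {len(exon)})")


class Gene:
    """A gene with lazily loaded transcripts."""

    def __init__(self, feature: Feature, stable_id: str,
                 biotype: str = "protein_coding", version: int = 1,
                 transcripts: Optional[list[Transcript]] = None,
                 internal_id: Optional[int] = None,
                 _store: Optional[Store] = None):
        if version < 1:
            raise ModelError(f"gene {stable_id}: version must be >= 1")
        self.feature = feature
        self.stable_id = stable_id
        self.biotype = biotype
        self.version = version
        self.internal_id = internal_id
        self._store = _store
        self._transcripts = transcripts

    @property
    def transcripts(self) -> list[Transcript]:
        if self._transcripts is None:
            if self._store is None or self.internal_id is None:
                raise ModelError(f"gene {self.stable_id} has no transcript source")
            self._transcripts = _load_transcripts(self._store, self.internal_id)
        return self._transcripts

    def __repr__(self):
        return f"<Gene {self.stable_id}.{self.version} {self.biotype}>"


# -- persistence -----------------------------------------------------------

def store_gene(store: Store, gene: Gene) -> int:
    """Persist a full gene graph; exons shared between transcripts are
    stored once (keyed by stable id)."""
    for t in gene.transcripts:
        t.validate()
    gene_feature_id = store.add_feature(gene.feature)
    cur = store.execute(
        "INSERT INTO gene(feature_id, stable_id, version, biotype) VALUES (?,?,?,?)",
        (gene_feature_id, gene.stable_id, gene.version, gene.biotype))
    gene_id = cur.lastrowid
    gene.internal_id = gene_id
    gene._store = store
    exon_ids: dict[str, int] = {}
    for t in gene.transcripts:
        t_feature_id = store.add_feature(t.feature)
        cur = store.execute(
            "INSERT INTO transcript(gene_id, feature_id, stable_id, version, biotype) "
            "VALUES (?,?,?,?,?)",
            (gene_id, t_feature_id, t.stable_id, t.version, t.biotype))
        t.internal_id = cur.lastrowid
        for rank, e in enumerate(t.exons, start=1):
            if e.stable_id not in exon_ids:
                e_feature_id = store.add_feature(e.feature)
                cur = store.execute(
                    "INSERT INTO exon(feature_id, stable_id, version, phase) "
                    "VALUES (?,?,?,?)",
                    (e_feature_id, e.stable_id, e.version, e.phase))
                exon_ids[e.stable_id] = cur.lastrowid
            e.internal_id = exon_ids[e.stable_id]
            store.execute(
                "INSERT INTO exon_transcript(exon_id, transcript_id, rank) "
                "VALUES (?,?,?)", (e.internal_id, t.internal_id, rank))
        if t.translation is not None:
            tr = t.translation
            cur = store.execute(
                "INSERT INTO translation(transcript_id, stable_id, version, "
                "start_exon_id, seq_start, end_exon_id, seq_end) "
                "VALUES (?,?,?,?,?,?,?)",
                (t.internal_id, tr.stable_id, tr.version,
                 exon_ids[tr.start_exon.stable_id], tr.seq_start,
                 exon_ids[tr.end_exon.stable_id], tr.seq_end))
            tr.internal_id = cur.lastrowid
    store.commit()
    return gene_id


def fetch_gene(store: Store, stable_id: str) -> Gene:
    """Fetch a gene shell; transcripts load on first access."""
    row = store.execute(
        "SELECT gene.*, feature.* FROM gene "
        "JOIN feature ON feature.feature_id = gene.feature_id "
        "WHERE gene.stable_id=?", (stable_id,)).fetchone()
    if row is None:
        raise StoreError(f"no gene with stable id {stable_id!r}")
    return Gene(feature=store.feature_from_row(row), stable_id=row["stable_id"],
                biotype=row["biotype"], version=row["version"],
                internal_id=row["gene_id"], _store=store)


def fetch_genes(store: Store, species_id: Optional[int] = None) -> list[Gene]:
    rows = store.execute(
        "SELECT stable_id FROM gene ORDER BY gene_id").fetchall()
    genes = [fetch_gene(store, r["stable_id"]) for r in rows]
    if species_id is not None:
        genes = [g for g in genes
                 if g.feature.region.coord_system.species_id == species_id]
    return genes


def _load_transcripts(store: Store, gene_id: int) -> list[Transcript]:
    out = []
    for trow in store.execute(
            "SELECT transcript.*, feature.* FROM transcript "
            "JOIN feature ON feature.feature_id = transcript.feature_id "
            "WHERE gene_id=? ORDER BY transcript_id", (gene_id,)).fetchall():
        exons = []
        by_exon_id = {}
        for erow in store.execute(
                "SELECT exon.*, feature.*, exon_transcript.rank FROM exon_transcript "
                "JOIN exon ON exon.exon_id = exon_transcript.exon_id "
                "JOIN feature ON feature.feature_id = exon.feature_id "
                "WHERE exon_transcript.transcript_id=? ORDER BY rank",
                (trow["transcript_id"],)).fetchall():
            exon = Exon(feature=store.feature_from_row(erow),
                        stable_id=erow["stable_id"], version=erow["version"],
                        phase=erow["phase"], internal_id=erow["exon_id"])
            exons.append(exon)
            by_exon_id[erow["exon_id"]] = exon
        translation = None
        prow = store.execute(
            "SELECT * FROM translation WHERE transcript_id=?",
            (trow["transcript_id"],)).fetchone()
        if prow is not None:
            translation = Translation(
                stable_id=prow["stable_id"], version=prow["version"],
                start_exon=by_exon_id[prow["start_exon_id"]],
                seq_start=prow["seq_start"],
                end_exon=by_exon_id[prow["end_exon_id"]],
                seq_end=prow["seq_end"], internal_id=prow["translation_id"])
        out.append(Transcript(
            feature=store.feature_from_row(trow), stable_id=trow["stable_id"],
            biotype=trow["biotype"], version=trow["version"], exons=exons,
            translation=translation, internal_id=trow["transcript_id"]))
    return out


# -- sequence computation --------------------------------------------------

def spliced_cdna(store: Store, t: Transcript) -> str:
    """Concatenated exon sequences in transcript (5'->3') order."""
    t.validate()
    parts = []
    for e in t.exons:
        f = e.feature
        if f.end > f.region.length or f.start < 1:
            raise ModelError(f"exon {e.stable_id} outside region bounds")
        parts.append(assembly.fetch_sequence(store, f.slice()))
    return "".join(parts)


def cds_sequence(store: Store, t: Transcript) -> Optional[str]:
    """The coding subsequence of the spliced cDNA, or None if non-coding."""
    if t.translation is None:
        return None
    cdna = spliced_cdna(store, t)
    tr = t.translation
    offset = 0
    cds_start = cds_end = None
    for e in t.exons:
        if e.stable_id == tr.start_exon.stable_id and cds_start is None:
            cds_start = offset + tr.seq_start
        if e.stable_id == tr.end_exon.stable_id:
            cds_end = offset + tr.seq_end
        offset += len(e)
    assert cds_start is not None and cds_end is not None
    return cdna[cds_start - 1:cds_end]


def translate(store: Store, t: Transcript) -> Optional[str]:
    """Standard-genetic-code protein for a coding transcript, else None.

    The trailing stop is removed; a CDS whose length is not a multiple of
    three is rejected as an incomplete codon.
    """
    cds = cds_sequence(store, t)
    if cds is None:
        return None
    if len(cds) % 3 != 0:
        raise ModelError(
            f"transcript {t.stable_id}: CDS length {len(cds)} is not a "
            f"multiple of 3 (incomplete codon)")
    protein = str(Seq(cds).translate(table=1))
    return protein[:-1] if protein.endswith("*") else protein


# -- operons ---------------------------------------------------------------

@dataclass
class OperonTranscript:
    feature: Feature
    display_label: str
    gene_stable_ids: list[str] = field(default_factory=list)
    internal_id: Optional[int] = None


@dataclass
class Operon:
    feature: Feature
    display_label: str
    transcripts: list[OperonTranscript] = field(default_factory=list)
    internal_id: Optional[int] = None


def store_operon(store: Store, operon: Operon) -> int:
    """Persist an operon with its polycistronic transcripts and gene links."""
    if not operon.transcripts:
        raise ModelError(
            f"operon {operon.display_label!r} must contain at least one "
            f"operon transcript")
    for ot in operon.transcripts:
        for gid in ot.gene_stable_ids:
            row = store.execute(
                "SELECT gene_id FROM gene WHERE stable_id=?", (gid,)).fetchone()
            if row is None:
                raise StoreError(
                    f"operon transcript {ot.display_label!r} links unknown "
                    f"gene {gid!r}")
    feature_id = store.add_feature(operon.feature)
    cur = store.execute(
        "INSERT INTO operon(feature_id, display_label) VALUES (?,?)",
        (feature_id, operon.display_label))
    operon.internal_id = cur.lastrowid
    for ot in operon.transcripts:
        ot_feature_id = store.add_feature(ot.feature)
        cur = store.execute(
            "INSERT INTO operon_transcript(operon_id, feature_id, display_label) "
            "VALUES (?,?,?)", (operon.internal_id, ot_feature_id, ot.display_label))
        ot.internal_id = cur.lastrowid
        for gid in ot.gene_stable_ids:
            store.execute(
                "INSERT INTO operon_transcript_gene(operon_transcript_id, "
                "gene_stable_id) VALUES (?,?)", (ot.internal_id, gid))
    store.commit()
    return operon.internal_id


def fetch_operon(store: Store, display_label: str) -> Operon:
    row = store.execute(
        "SELECT operon.*, feature.* FROM operon "
        "JOIN feature ON feature.feature_id = operon.feature_id "
        "WHERE display_label=?", (display_label,)).fetchone()
    if row is None:
        raise StoreError(f"no operon labelled {display_label!r}")
    operon = Operon(feature=store.feature_from_row(row),
                    display_label=row["display_label"],
                    internal_id=row["operon_id"])
    for ot_row in store.execute(
            "SELECT operon_transcript.*, feature.* FROM operon_transcript "
            "JOIN feature ON feature.feature_id = operon_transcript.feature_id "
            "WHERE operon_id=? ORDER BY operon_transcript_id",
            (operon.internal_id,)).fetchall():
        genes = [r["gene_stable_id"] for r in store.execute(
            "SELECT gene_stable_id FROM operon_transcript_gene "
            "WHERE operon_transcript_id=? ORDER BY rowid",
            (ot_row["operon_transcript_id"],))]
        operon.transcripts.append(OperonTranscript(
            feature=store.feature_from_row(ot_row),
            display_label=ot_row["display_label"], gene_stable_ids=genes,
            internal_id=ot_row["operon_transcript_id"]))
    return operon


def operon_products(store: Store, operon: Operon) -> list[tuple[OperonTranscript, list[str]]]:
    """Each operon transcript with its linked gene stable ids, in stored order.

    A link to a gene no longer present in the store is an error (dangling
    link), since every polypeptide of a polycistronic mRNA must have its own
    gene record.
    """
    out = []
    for ot in operon.transcripts:
        for gid in ot.gene_stable_ids:
            row = store.execute(
                "SELECT gene_id FROM gene WHERE stable_id=?", (gid,)).fetchone()
            if row is None:
                raise StoreError(
                    f"dangling gene link {gid!r} on operon transcript "
                    f"{ot.display_label!r}")
        out.append((ot, list(ot.gene_stable_ids)))
    return out
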