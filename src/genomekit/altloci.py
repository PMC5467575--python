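"""Assembly exceptions: PARs, patches and alternate haplotypes.

An assembly exception declares that a range of one region (the exception
side) substitutes for a range of a reference region, so the substituted
sequence and annotation are stored only once:

* PAR — the pseudo-autosomal case: the exception region (e.g. Y) is a real
  chromosome whose PAR ranges carry no sequence or annotation of their own;
  both are projected from the reference (X) range on demand.  Exception and
  reference ranges must have equal length.
* PATCH_FIX / PATCH_NOVEL / HAP — the exception region is presented as a
  whole virtual chromosome: the reference chromosome with the replaced range
  swapped for the exception's own (possibly longer or shorter) sequence.
  Feature coordinates on the exception region are expressed relative to that
  entire virtual chromosome, so annotation downstream of the exception
  shifts by the cumulative length difference.

Annotation crossing an exception boundary is stored twice (once per side);
queries across a boundary merge the flanking and exception sub-queries and
collapse such duplicates to a single result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from . import assembly, features
from .model import Feature, ModelError, SeqRegion, Slice
from .store import Store, StoreError

EXC_TYPES = ("PAR", "PATCH_FIX", "PATCH_NOVEL", "HAP")


@dataclass(frozen=True)
class AssemblyException:
    exc_type: str
    exc_region: SeqRegion
    exc_start: int
    exc_end: int
    ref_region: SeqRegion
    ref_start: int
    ref_end: int
    internal_id: Optional[int] = None

    def __post_init__(self):
        if self.exc_type not in EXC_TYPES:
            raise ModelError(f"unknown exception type {self.exc_type!r}")
        if self.exc_start > self.exc_end or self.ref_start > self.ref_end:
            raise ModelError("exception range start must not exceed end")
        if self.exc_type == "PAR" and self.exc_len != self.ref_len:
            raise ModelError(
                f"PAR ranges must have equal length (pure substitution): "
                f"{self.exc_len} vs {self.ref_len}")

    @property
    def exc_len(self) -> int:
        return self.exc_end - self.exc_start + 1

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def length_delta(self) -> int:
        return self.exc_len - self.ref_len


def register_exception(store: Store, exc: AssemblyException) -> int:
    """Store an exception record; exception-side ranges on one region must
    not overlap one another."""
    for other in exceptions_on(store, exc.exc_region):
        if exc.exc_start <= other.exc_end and exc.exc_end >= other.exc_start:
            raise StoreError(
                f"exception ranges overlap on {exc.exc_region.name!r}: "
                f"{exc.exc_start}-{exc.exc_end} vs {other.exc_start}-{other.exc_end}")
    cur = store.execute(
        "INSERT INTO assembly_exception(exc_type, exc_seq_region_id, exc_start, "
        "exc_end, ref_seq_region_id, ref_start, ref_end) VALUES (?,?,?,?,?,?,?)",
        (exc.exc_type, exc.exc_region.internal_id, exc.exc_start, exc.exc_end,
         exc.ref_region.internal_id, exc.ref_start, exc.ref_end))
    store.commit()
    return cur.lastrowid


def exceptions_on(store: Store, exc_region: SeqRegion) -> list[AssemblyException]:
    rows = store.execute(
        "SELECT * FROM assembly_exception WHERE exc_seq_region_id=? "
        "ORDER BY exc_start", (exc_region.internal_id,)).fetchall()
    return [AssemblyException(
        exc_type=r["exc_type"],
        exc_region=store.region_by_id(r["exc_seq_region_id"]),
        exc_start=r["exc_start"], exc_end=r["exc_end"],
        ref_region=store.region_by_id(r["ref_seq_region_id"]),
        ref_start=r["ref_start"], ref_end=r["ref_end"],
        internal_id=r["assembly_exception_id"]) for r in rows]


@dataclass(frozen=True)
class _Piece:
    """One contiguous stretch of the presented chromosome and its source."""
    virt_start: int
    virt_end: int
    source_region: SeqRegion
    src_start: int
    src_end: int
    exc: Optional[AssemblyException] = None  # None for flanking pieces

    @property
    def offset(self) -> int:
        """virtual position = source position + offset"""
        return self.virt_start - self.src_start


class ExceptionView:
    """Whole-chromosome presentation of a region carrying assembly exceptions."""

    def __init__(self, store: Store, exc_region: SeqRegion):
        excs = exceptions_on(store, exc_region)
        if not excs:
            raise StoreError(
                f"region {exc_region.name!r} has no registered assembly exceptions")
        types = {e.exc_type for e in excs}
        if "PAR" in types and types != {"PAR"}:
            raise ModelError(
                f"region {exc_region.name!r} mixes PAR and patch exceptions")
        self.store = store
        self.exc_region = exc_region
        self.is_par = types == {"PAR"}
        self.pieces: list[_Piece] = []
        if self.is_par:
            self._build_par(excs)
        else:
            self._build_patch(excs)
        self.length = self.pieces[-1].virt_end
        # presentation handle: the exception region at its virtual length
        self.region = replace(exc_region, length=self.length)

    def _build_par(self, excs: list[AssemblyException]) -> None:
        # the exception region is real; only the PAR ranges are substituted
        cursor = 1
        for e in excs:
            if e.exc_start > cursor:
                self.pieces.append(_Piece(cursor, e.exc_start - 1,
                                          self.exc_region, cursor, e.exc_start - 1))
            self.pieces.append(_Piece(e.exc_start, e.exc_end,
                                      e.ref_region, e.ref_start, e.ref_end, e))
            cursor = e.exc_end + 1
        if cursor <= self.exc_region.length:
            self.pieces.append(_Piece(cursor, self.exc_region.length,
                                      self.exc_region, cursor,
                                      self.exc_region.length))

    def _build_patch(self, excs: list[AssemblyException]) -> None:
        # virtual chromosome: the reference chromosome with replaced ranges
        refs = {e.ref_region.internal_id for e in excs}
        if len(refs) != 1:
            raise ModelError(
                f"patch region {self.exc_region.name!r} references several "
                f"chromosomes")
        ref = excs[0].ref_region
        prev_exc_end = prev_ref_end = 0
        for e in sorted(excs, key=lambda x: x.ref_start):
            if e.exc_start - prev_exc_end != e.ref_start - prev_ref_end:
                raise ModelError(
                    f"inconsistent flank lengths before exception at "
                    f"{self.exc_region.name}:{e.exc_start}")
            if e.ref_start - 1 > prev_ref_end:
                self.pieces.append(_Piece(prev_exc_end + 1, e.exc_start - 1,
                                          ref, prev_ref_end + 1, e.ref_start - 1))
            # the patch's own storage already uses whole-chromosome coordinates
            self.pieces.append(_Piece(e.exc_start, e.exc_end,
                                      self.exc_region, e.exc_start, e.exc_end, e))
            prev_exc_end, prev_ref_end = e.exc_end, e.ref_end
        if prev_ref_end < ref.length:
            delta = prev_exc_end - prev_ref_end
            self.pieces.append(_Piece(prev_ref_end + 1 + delta, ref.length + delta,
                                      ref, prev_ref_end + 1, ref.length))

    def slice(self) -> Slice:
        """The whole virtual chromosome as a queryable slice."""
        return Slice(self.region, 1, self.length)


def exception_slice(store: Store, exc_region: SeqRegion) -> Slice:
    """Whole-chromosome slice for a region carrying assembly exceptions.

    For patches the slice length is the reference chromosome length plus the
    sum of exception-minus-reference length differences; for PARs it is the
    exception chromosome's own length.
    """
    return ExceptionView(store, exc_region).slice()


def _dedup_key(f: Feature):
    if f.stable_id:
        return ("id", f.stable_id)
    return ("coords", f.feature_type, f.start, f.end, f.strand)


def fetch_across_exception(store: Store, view: ExceptionView, start: int,
                           end: int, feature_type: str) -> list[Feature]:
    """Features overlapping a virtual-chromosome range.

    Searches the flanking pieces of the main assembly and the exception
    pieces separately, shifts every hit into whole-chromosome coordinates
    (full extent, unclipped) and discards duplicates — annotation crossing a
    boundary is stored on both sides and must be returned once.
    """
    hits: list[Feature] = []
    for piece in view.pieces:
        if piece.virt_start > end or piece.virt_end < start:
            continue
        q_lo = max(piece.src_start, start - piece.offset)
        q_hi = min(piece.src_end, end - piece.offset)
        if q_lo > q_hi:
            continue
        for f in features.fetch_overlapping(
                store, Slice(piece.source_region, q_lo, q_hi), feature_type):
            g = Feature(
                feature_type=f.feature_type, region=view.region,
                start=f.start + piece.offset, end=f.end + piece.offset,
                strand=f.strand, analysis=f.analysis,
                attributes=dict(f.attributes), stable_id=f.stable_id,
                version=f.version, internal_id=f.internal_id)
            hits.append(g)
    hits.sort(key=lambda f: (f.start, f.end, f.stable_id or "", f.internal_id or 0))
    seen = set()
    out = []
    for f in hits:
        key = _dedup_key(f)
        if key in seen:
            continue
        seen.add(key)
        out.append(f)
    return out


def fetch_par_features(store: Store, par_slice: Slice,
                       feature_type: str) -> list[Feature]:
    """Features for a slice on a PAR-carrying chromosome (e.g. Y).

    Inside a PAR the annotation lives on the reference chromosome (X) and is
    projected over, shifted by (exception start - reference start); outside
    all PARs this is a plain fetch.
    """
    region = par_slice.region
    if not exceptions_on(store, region):
        return features.fetch_overlapping(store, par_slice, feature_type)
    view = ExceptionView(store, region)
    return fetch_across_exception(store, view, par_slice.start, par_slice.end,
                                  feature_type)


def fetch_exception_sequence(store: Store, view: ExceptionView, start: int,
                             end: int, strand: int = 1) -> str:
    """Sequence of a virtual-chromosome range, assembled piecewise from the
    reference chromosome and the exception region's own storage."""
    chunks = []
    for piece in view.pieces:
        if piece.virt_start > end or piece.virt_end < start:
            continue
        q_lo = max(piece.src_start, start - piece.offset)
        q_hi = min(piece.src_end, end - piece.offset)
        chunks.append(assembly.fetch_sequence(
            store, Slice(piece.source_region, q_lo, q_hi)))
    seq = "".join(chunks)
    return assembly.revcomp(seq) if strand == -1 else seq


# -- alternative alleles ---------------------------------------------------

ALT_ALLELE_FLAGS = ("manual", "automatic", "sequencing_error",
                    "individual_variability")


@dataclass
class AltAlleleMember:
    gene_stable_id: str
    is_reference: bool = False
    flags: tuple = ()


@dataclass
class AltAlleleGroup:
    """Gene copies representing one locus on reference and exception regions,
    with a nominated reference copy."""
    members: list[AltAlleleMember] = field(default_factory=list)
    internal_id: Optional[int] = None

    def validate(self) -> None:
        if len(self.members) < 2:
            raise ModelError("an alt-allele group needs at least two members")
        n_ref = sum(m.is_reference for m in self.members)
        if n_ref != 1:
            raise ModelError(
                f"an alt-allele group needs exactly one reference member, "
                f"found {n_ref}")
        for m in self.members:
            for flag in m.flags:
                if flag not in ALT_ALLELE_FLAGS:
                    raise ModelError(f"unknown alt-allele flag {flag!r}")


def store_alt_allele_group(store: Store, group: AltAlleleGroup) -> int:
    group.validate()
    for m in group.members:
        row = store.execute("SELECT gene_id FROM gene WHERE stable_id=?",
                            (m.gene_stable_id,)).fetchone()
        if row is None:
            raise StoreError(f"alt-allele member {m.gene_stable_id!r} is not a "
                             f"stored gene")
    cur = store.execute("INSERT INTO alt_allele_group DEFAULT VALUES")
    gid = cur.lastrowid
    for m in group.members:
        store.execute(
            "INSERT INTO alt_allele(alt_allele_group_id, gene_stable_id, "
            "is_reference, flags) VALUES (?,?,?,?)",
            (gid, m.gene_stable_id, int(m.is_reference), ",".join(m.flags)))
    store.commit()
    group.internal_id = gid
    return gid


def alt_allele_group(store: Store, gene_stable_id: str) -> Optional[AltAlleleGroup]:
    """The alt-allele group containing a gene, or None for singletons."""
    row = store.execute(
        "SELECT alt_allele_group_id FROM alt_allele WHERE gene_stable_id=?",
        (gene_stable_id,)).fetchone()
    if row is None:
        return None
    gid = row["alt_allele_group_id"]
    members = [AltAlleleMember(
        gene_stable_id=r["gene_stable_id"],
        is_reference=bool(r["is_reference"]),
        flags=tuple(r["flags"].split(",")) if r["flags"] else ())
        for r in store.execute(
            "SELECT * FROM alt_allele WHERE alt_allele_group_id=? ORDER BY rowid",
            (gid,))]
    return AltAlleleGroup(members=members, internal_id=gid)
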