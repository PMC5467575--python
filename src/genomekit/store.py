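"""Single-file embedded relational store.

The schema mirrors the classic core annotation layout: ``coord_system``,
``seq_region``, ``assembly``, ``meta``, ``meta_coord`` and
``seq_region_attrib``, plus feature, gene-model, assembly-exception,
stable-ID-event and cross-reference tables.  All feature tables are indexed
by (feature type, sequence region, start) so that regional queries are a
bounded B-tree scan (see :mod:`genomekit.features`).
"""

from __future__ import annotations

import json
import sqlite3
from typing import Iterable, Optional, Sequence

from .model import (
    AssemblySegment,
    CoordSystem,
    Feature,
    ModelError,
    SeqRegion,
    feature_length,
)

_SCHEMA = """
CREATE TABLE coord_system(
  coord_system_id INTEGER PRIMARY KEY,
  species_id INTEGER NOT NULL DEFAULT 1,
  name TEXT NOT NULL,
  version TEXT,
  rank INTEGER NOT NULL,
  sequence_level INTEGER NOT NULL DEFAULT 0,
  is_default INTEGER NOT NULL DEFAULT 1
);
CREATE UNIQUE INDEX cs_key ON coord_system(name, IFNULL(version,''), species_id);
CREATE TABLE seq_region(
  seq_region_id INTEGER PRIMARY KEY,
  name TEXT NOT NULL,
  coord_system_id INTEGER NOT NULL REFERENCES coord_system(coord_system_id),
  length INTEGER NOT NULL,
  UNIQUE(name, coord_system_id)
);
CREATE TABLE seq_region_attrib(
  seq_region_id INTEGER NOT NULL,
  code TEXT NOT NULL,
  value TEXT NOT NULL,
  UNIQUE(seq_region_id, code)
);
CREATE TABLE dna(
  seq_region_id INTEGER PRIMARY KEY,
  sequence TEXT NOT NULL
);
CREATE TABLE assembly(
  asm_seq_region_id INTEGER NOT NULL,
  asm_start INTEGER NOT NULL,
  asm_end INTEGER NOT NULL,
  cmp_seq_region_id INTEGER NOT NULL,
  cmp_start INTEGER NOT NULL,
  cmp_end INTEGER NOT NULL,
  ori INTEGER NOT NULL
);
CREATE INDEX assembly_asm ON assembly(asm_seq_region_id, asm_start);
CREATE INDEX assembly_cmp ON assembly(cmp_seq_region_id, cmp_start);
CREATE TABLE meta(
  species_id INTEGER,
  meta_key TEXT NOT NULL,
  meta_value TEXT NOT NULL
);
CREATE TABLE meta_coord(
  feature_type TEXT NOT NULL,
  coord_system_id INTEGER NOT NULL,
  max_length INTEGER NOT NULL,
  UNIQUE(feature_type, coord_system_id)
);
CREATE TABLE feature(
  feature_id INTEGER PRIMARY KEY,
  feature_type TEXT NOT NULL,
  seq_region_id INTEGER NOT NULL,
  seq_region_start INTEGER NOT NULL,
  seq_region_end INTEGER NOT NULL,
  seq_region_strand INTEGER NOT NULL,
  analysis TEXT,
  stable_id TEXT,
  version INTEGER,
  attribs TEXT
);
CREATE INDEX feature_region_start
  ON feature(feature_type, seq_region_id, seq_region_start);
CREATE TABLE gene(
  gene_id INTEGER PRIMARY KEY,
  feature_id INTEGER NOT NULL,
  stable_id TEXT UNIQUE,
  version INTEGER,
  biotype TEXT
);
CREATE TABLE transcript(
  transcript_id INTEGER PRIMARY KEY,
  gene_id INTEGER NOT NULL,
  feature_id INTEGER NOT NULL,
  stable_id TEXT UNIQUE,
  version INTEGER,
  biotype TEXT
);
CREATE TABLE exon(
  exon_id INTEGER PRIMARY KEY,
  feature_id INTEGER NOT NULL,
  stable_id TEXT,
  version INTEGER,
  phase INTEGER
);
CREATE TABLE exon_transcript(
  exon_id INTEGER NOT NULL,
  transcript_id INTEGER NOT NULL,
  rank INTEGER NOT NULL,
  UNIQUE(transcript_id, rank)
);
CREATE TABLE translation(
  translation_id INTEGER PRIMARY KEY,
  transcript_id INTEGER NOT NULL UNIQUE,
  stable_id TEXT,
  version INTEGER,
  start_exon_id INTEGER NOT NULL,
  seq_start INTEGER NOT NULL,
  end_exon_id INTEGER NOT NULL,
  seq_end INTEGER NOT NULL
);
CREATE TABLE operon(
  operon_id INTEGER PRIMARY KEY,
  feature_id INTEGER NOT NULL,
  display_label TEXT
);
CREATE TABLE operon_transcript(
  operon_transcript_id INTEGER PRIMARY KEY,
  operon_id INTEGER NOT NULL,
  feature_id INTEGER NOT NULL,
  display_label TEXT
);
CREATE TABLE operon_transcript_gene(
  operon_transcript_id INTEGER NOT NULL,
  gene_stable_id TEXT NOT NULL
);
CREATE TABLE assembly_exception(
  assembly_exception_id INTEGER PRIMARY KEY,
  exc_type TEXT NOT NULL,
  exc_seq_region_id INTEGER NOT NULL,
  exc_start INTEGER NOT NULL,
  exc_end INTEGER NOT NULL,
  ref_seq_region_id INTEGER NOT NULL,
  ref_start INTEGER NOT NULL,
  ref_end INTEGER NOT NULL
);
CREATE TABLE alt_allele_group(
  alt_allele_group_id INTEGER PRIMARY KEY
);
CREATE TABLE alt_allele(
  alt_allele_group_id INTEGER NOT NULL,
  gene_stable_id TEXT NOT NULL UNIQUE,
  is_reference INTEGER NOT NULL DEFAULT 0,
  flags TEXT
);
CREATE TABLE mapping_session(
  mapping_session_id INTEGER PRIMARY KEY,
  source TEXT NOT NULL,
  target TEXT NOT NULL,
  same_assembly INTEGER NOT NULL,
  created TEXT,
  seed INTEGER DEFAULT 0
);
CREATE TABLE stable_id_event(
  mapping_session_id INTEGER NOT NULL,
  object_type TEXT NOT NULL,
  old_stable_id TEXT,
  old_version INTEGER,
  new_stable_id TEXT,
  new_version INTEGER,
  score REAL
);
CREATE TABLE xref(
  xref_id INTEGER PRIMARY KEY,
  source TEXT NOT NULL,
  accession TEXT NOT NULL,
  display_label TEXT,
  info_type TEXT NOT NULL,
  query_identity REAL,
  target_identity REAL,
  cigar TEXT,
  evidence_code TEXT
);
CREATE TABLE object_xref(
  xref_id INTEGER NOT NULL,
  object_type TEXT NOT NULL,
  object_stable_id TEXT NOT NULL
);
CREATE TABLE data_file(
  data_file_id INTEGER PRIMARY KEY,
  species TEXT NOT NULL,
  assembly TEXT NOT NULL,
  analysis TEXT NOT NULL,
  name TEXT NOT NULL,
  file_type TEXT NOT NULL,
  versioned INTEGER NOT NULL DEFAULT 0,
  version INTEGER,
  UNIQUE(species, assembly, analysis, name)
);
"""


class StoreError(ModelError):
    """Raised on store-level constraint violations."""


class Store:
    """An embedded annotation store (sqlite file or in-memory).

    Every executed SELECT increments :attr:`query_count`, which makes
    lazy-loading behaviour observable.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.row_factory = sqlite3.Row
        self.query_count = 0
        if not self._has_schema():
            self.conn.executescript(_SCHEMA)
            self.conn.commit()
        self._cs_cache: dict[int, CoordSystem] = {}
        self._region_cache: dict[int, SeqRegion] = {}

    # -- low-level ---------------------------------------------------------

    def _has_schema(self) -> bool:
        row = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='coord_system'"
        ).fetchone()
        return row is not None

    def execute(self, sql: str, params: Sequence = ()) -> sqlite3.Cursor:
        if sql.lstrip().upper().startswith("SELECT"):
            self.query_count += 1
        return self.conn.execute(sql, params)

    def commit(self) -> None:
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- coordinate systems ------------------------------------------------

    def add_coord_system(self, cs: CoordSystem) -> CoordSystem:
        for other in self.coord_systems(species_id=cs.species_id):
            if other.key == cs.key:
                raise StoreError(f"coord system {cs.key} already registered")
            if other.rank == cs.rank:
                raise StoreError(
                    f"rank {cs.rank} already used by coord system {other.name!r}"
                )
            if cs.is_sequence_level and other.is_sequence_level:
                raise StoreError(
                    f"species {cs.species_id} already has sequence-level coord "
                    f"system {other.name!r}"
                )
        cur = self.execute(
            "INSERT INTO coord_system(species_id, name, version, rank, "
            "sequence_level, is_default) VALUES (?,?,?,?,?,?)",
            (cs.species_id, cs.name, cs.version, cs.rank,
             int(cs.is_sequence_level), int(cs.is_default)),
        )
        self.commit()
        stored = CoordSystem(
            name=cs.name, version=cs.version, rank=cs.rank,
            species_id=cs.species_id, is_sequence_level=cs.is_sequence_level,
            is_default=cs.is_default, internal_id=cur.lastrowid,
        )
        self._cs_cache[cur.lastrowid] = stored
        return stored

    def _cs_from_row(self, row: sqlite3.Row) -> CoordSystem:
        cid = row["coord_system_id"]
        if cid not in self._cs_cache:
            self._cs_cache[cid] = CoordSystem(
                name=row["name"], version=row["version"], rank=row["rank"],
                species_id=row["species_id"],
                is_sequence_level=bool(row["sequence_level"]),
                is_default=bool(row["is_default"]), internal_id=cid,
            )
        return self._cs_cache[cid]

    def coord_systems(self, species_id: Optional[int] = None) -> list[CoordSystem]:
        sql = "SELECT * FROM coord_system"
        params: tuple = ()
        if species_id is not None:
            sql += " WHERE species_id=?"
            params = (species_id,)
        return [self._cs_from_row(r) for r in self.execute(sql + " ORDER BY rank", params)]

    def coord_system(self, name: str, version: Optional[str] = None,
                     species_id: int = 1) -> CoordSystem:
        for cs in self.coord_systems(species_id=species_id):
            if cs.name == name and (version is None or cs.version == version):
                return cs
        raise StoreError(f"unknown coord system {name!r} (version {version!r})")

    def coord_system_by_id(self, cid: int) -> CoordSystem:
        if cid in self._cs_cache:
            return self._cs_cache[cid]
        row = self.execute(
            "SELECT * FROM coord_system WHERE coord_system_id=?", (cid,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no coord system with id {cid}")
        return self._cs_from_row(row)

    def sequence_level_cs(self, species_id: int = 1) -> CoordSystem:
        for cs in self.coord_systems(species_id=species_id):
            if cs.is_sequence_level:
                return cs
        raise StoreError(f"species {species_id} has no sequence-level coord system")

    # -- sequence regions --------------------------------------------------

    def add_seq_region(self, name: str, cs: CoordSystem, length: int,
                       circular: bool = False,
                       sequence: Optional[str] = None) -> SeqRegion:
        if cs.internal_id is None:
            raise StoreError("coord system must be registered first")
        cur = self.execute(
            "INSERT INTO seq_region(name, coord_system_id, length) VALUES (?,?,?)",
            (name, cs.internal_id, length),
        )
        rid = cur.lastrowid
        if circular:
            self.set_region_attrib(rid, "circular", "1")
        # a fresh region has no parents, hence toplevel until assembled into one
        self.set_region_attrib(rid, "toplevel", "1")
        region = SeqRegion(name=name, coord_system=cs, length=length,
                           is_circular=circular, is_toplevel=True, internal_id=rid)
        self._region_cache[rid] = region
        if sequence is not None:
            self.set_sequence(region, sequence)
        self.commit()
        return region

    def set_region_attrib(self, seq_region_id: int, code: str, value: str) -> None:
        self.execute(
            "INSERT OR REPLACE INTO seq_region_attrib(seq_region_id, code, value) "
            "VALUES (?,?,?)", (seq_region_id, code, value))

    def region_attrib(self, seq_region_id: int, code: str) -> Optional[str]:
        row = self.execute(
            "SELECT value FROM seq_region_attrib WHERE seq_region_id=? AND code=?",
            (seq_region_id, code)).fetchone()
        return row["value"] if row else None

    def _region_from_row(self, row: sqlite3.Row) -> SeqRegion:
        rid = row["seq_region_id"]
        if rid not in self._region_cache:
            cs = self.coord_system_by_id(row["coord_system_id"])
            self._region_cache[rid] = SeqRegion(
                name=row["name"], coord_system=cs, length=row["length"],
                is_circular=self.region_attrib(rid, "circular") == "1",
                is_toplevel=self.region_attrib(rid, "toplevel") == "1",
                internal_id=rid,
            )
        return self._region_cache[rid]

    def region(self, name: str, cs: CoordSystem) -> SeqRegion:
        row = self.execute(
            "SELECT * FROM seq_region WHERE name=? AND coord_system_id=?",
            (name, cs.internal_id)).fetchone()
        if row is None:
            raise StoreError(f"unknown region {name!r} in coord system {cs.name!r}")
        return self._region_from_row(row)

    def region_by_id(self, rid: int) -> SeqRegion:
        if rid in self._region_cache:
            return self._region_cache[rid]
        row = self.execute(
            "SELECT * FROM seq_region WHERE seq_region_id=?", (rid,)).fetchone()
        if row is None:
            raise StoreError(f"no seq region with id {rid}")
        return self._region_from_row(row)

    def regions(self, cs: Optional[CoordSystem] = None,
                species_id: Optional[int] = None) -> list[SeqRegion]:
        if cs is not None:
            rows = self.execute(
                "SELECT * FROM seq_region WHERE coord_system_id=? ORDER BY name",
                (cs.internal_id,))
        else:
            rows = self.execute("SELECT * FROM seq_region ORDER BY seq_region_id")
        out = [self._region_from_row(r) for r in rows]
        if species_id is not None:
            out = [r for r in out if r.coord_system.species_id == species_id]
        return out

    def set_sequence(self, region: SeqRegion, sequence: str) -> None:
        if not region.coord_system.is_sequence_level:
            raise StoreError(
                f"sequence may only be stored on the sequence-level coordinate "
                f"system, not {region.coord_system.name!r}")
        if len(sequence) != region.length:
            raise StoreError(
                f"sequence length {len(sequence)} != region length {region.length}")
        self.execute(
            "INSERT OR REPLACE INTO dna(seq_region_id, sequence) VALUES (?,?)",
            (region.internal_id, sequence))
        self.commit()

    def sequence(self, region: SeqRegion) -> Optional[str]:
        row = self.execute(
            "SELECT sequence FROM dna WHERE seq_region_id=?",
            (region.internal_id,)).fetchone()
        return row["sequence"] if row else None

    def total_sequence_bytes(self) -> int:
        row = self.execute("SELECT IFNULL(SUM(LENGTH(sequence)),0) n FROM dna").fetchone()
        return row["n"]

    # -- assembly hierarchy ------------------------------------------------

    def register_assembly(self, segments: Iterable[AssemblySegment]) -> int:
        """Store AGP-like rows and recompute toplevel flags.

        Rejects rows whose assembled-side ranges overlap existing or sibling
        rows on the same region, naming the colliding pair.
        """
        segments = list(segments)
        if not segments:
            return 0
        # overlap on the assembled side is checked per target coordinate
        # system: contig rows and cross-version mapping rows legitimately
        # cover the same chromosome span
        by_region: dict[tuple, list[tuple[int, int, str]]] = {}
        for row in self.execute(
                "SELECT asm_seq_region_id, asm_start, asm_end, cmp_seq_region_id "
                "FROM assembly"):
            cmp_r = self.region_by_id(row["cmp_seq_region_id"])
            key = (row["asm_seq_region_id"], cmp_r.coord_system.internal_id)
            by_region.setdefault(key, []).append(
                (row["asm_start"], row["asm_end"], cmp_r.name))
        for seg in segments:
            if seg.asm_region.internal_id is None or seg.cmp_region.internal_id is None:
                raise StoreError("assembly segments must reference stored regions")
            existing = by_region.setdefault(
                (seg.asm_region.internal_id,
                 seg.cmp_region.coord_system.internal_id), [])
            for (s, e, other) in existing:
                if seg.asm_start <= e and seg.asm_end >= s:
                    raise StoreError(
                        f"assembled ranges overlap on {seg.asm_region.name!r}: "
                        f"{seg.asm_start}-{seg.asm_end} ({seg.cmp_region.name}) vs "
                        f"{s}-{e} ({other})")
            existing.append((seg.asm_start, seg.asm_end, seg.cmp_region.name))
        self.conn.executemany(
            "INSERT INTO assembly VALUES (?,?,?,?,?,?,?)",
            [(s.asm_region.internal_id, s.asm_start, s.asm_end,
              s.cmp_region.internal_id, s.cmp_start, s.cmp_end, s.ori)
             for s in segments])
        self.recompute_toplevel()
        self.commit()
        return len(segments)

    def assembly_segments(self, asm_region: Optional[SeqRegion] = None,
                          cmp_region: Optional[SeqRegion] = None) -> list[AssemblySegment]:
        sql = "SELECT * FROM assembly"
        clauses, params = [], []
        if asm_region is not None:
            clauses.append("asm_seq_region_id=?")
            params.append(asm_region.internal_id)
        if cmp_region is not None:
            clauses.append("cmp_seq_region_id=?")
            params.append(cmp_region.internal_id)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY asm_seq_region_id, asm_start"
        return [
            AssemblySegment(
                asm_region=self.region_by_id(r["asm_seq_region_id"]),
                asm_start=r["asm_start"], asm_end=r["asm_end"],
                cmp_region=self.region_by_id(r["cmp_seq_region_id"]),
                cmp_start=r["cmp_start"], cmp_end=r["cmp_end"], ori=r["ori"])
            for r in self.execute(sql, params)]

    def recompute_toplevel(self) -> None:
        """A region is toplevel iff it never appears as a component."""
        component_ids = {r["cmp_seq_region_id"] for r in
                         self.execute("SELECT DISTINCT cmp_seq_region_id FROM assembly")}
        for row in self.execute("SELECT seq_region_id FROM seq_region"):
            rid = row["seq_region_id"]
            flag = "0" if rid in component_ids else "1"
            if self.region_attrib(rid, "toplevel") != flag:
                self.set_region_attrib(rid, "toplevel", flag)
                self._region_cache.pop(rid, None)

    # -- meta & meta_coord -------------------------------------------------

    def set_meta(self, key: str, value: str, species_id: Optional[int] = None) -> None:
        self.execute("INSERT INTO meta(species_id, meta_key, meta_value) VALUES (?,?,?)",
                     (species_id, key, value))
        self.commit()

    def meta(self, key: str, species_id: Optional[int] = None) -> list[str]:
        if species_id is None:
            rows = self.execute(
                "SELECT meta_value FROM meta WHERE meta_key=?", (key,))
        else:
            rows = self.execute(
                "SELECT meta_value FROM meta WHERE meta_key=? AND species_id=?",
                (key, species_id))
        return [r["meta_value"] for r in rows]

    def add_species(self, name: str, species_id: int = 1) -> None:
        self.set_meta("species.name", name, species_id=species_id)

    def species(self) -> list[tuple[int, str]]:
        rows = self.execute(
            "SELECT species_id, meta_value FROM meta WHERE meta_key='species.name' "
            "ORDER BY species_id")
        return [(r["species_id"], r["meta_value"]) for r in rows]

    def max_feature_length(self, feature_type: str, cs: CoordSystem) -> Optional[int]:
        row = self.execute(
            "SELECT max_length FROM meta_coord WHERE feature_type=? AND coord_system_id=?",
            (feature_type, cs.internal_id)).fetchone()
        return row["max_length"] if row else None

    def raise_max_feature_length(self, feature_type: str, cs: CoordSystem,
                                 length: int) -> None:
        # never lowered: a stale upper bound only widens the scan window
        current = self.max_feature_length(feature_type, cs)
        if current is None:
            self.execute("INSERT INTO meta_coord VALUES (?,?,?)",
                         (feature_type, cs.internal_id, length))
        elif length > current:
            self.execute(
                "UPDATE meta_coord SET max_length=? WHERE feature_type=? AND "
                "coord_system_id=?", (length, feature_type, cs.internal_id))

    # -- features ----------------------------------------------------------

    def add_feature(self, f: Feature) -> int:
        if not f.region.is_toplevel:
            raise StoreError(
                f"features are stored on toplevel regions only; "
                f"{f.region.name!r} is a component — project the feature to a "
                f"toplevel coordinate system first")
        cur = self.execute(
            "INSERT INTO feature(feature_type, seq_region_id, seq_region_start, "
            "seq_region_end, seq_region_strand, analysis, stable_id, version, attribs) "
            "VALUES (?,?,?,?,?,?,?,?,?)",
            (f.feature_type, f.region.internal_id, f.start, f.end, f.strand,
             f.analysis, f.stable_id, f.version,
             json.dumps(f.attributes) if f.attributes else None))
        f.internal_id = cur.lastrowid
        self.raise_max_feature_length(
            f.feature_type, f.region.coord_system,
            feature_length(f.start, f.end, f.region.length))
        self.commit()
        return f.internal_id

    def feature_from_row(self, row: sqlite3.Row) -> Feature:
        return Feature(
            feature_type=row["feature_type"],
            region=self.region_by_id(row["seq_region_id"]),
            start=row["seq_region_start"], end=row["seq_region_end"],
            strand=row["seq_region_strand"], analysis=row["analysis"] or "manual",
            attributes=json.loads(row["attribs"]) if row["attribs"] else {},
            stable_id=row["stable_id"], version=row["version"],
            internal_id=row["feature_id"])

    def feature_by_id(self, feature_id: int) -> Feature:
        row = self.execute("SELECT * FROM feature WHERE feature_id=?",
                           (feature_id,)).fetchone()
        if row is None:
            raise StoreError(f"no feature with id {feature_id}")
        return self.feature_from_row(row)
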