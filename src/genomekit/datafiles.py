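"""Metadata-driven path construction for large indexed files.

Read alignments and coverage tracks are kept outside the relational store
in BAM/BigWig/BigBED files; a data-file record holds just enough metadata
(species, assembly version, analysis, name, type, optional version) to
rebuild a deterministic POSIX path.  BAMCOV pairs a BAM file with its
pre-computed coverage in a BigWig alongside.
"""

from __future__ import annotations

import posixpath
from dataclasses import dataclass
from typing import Optional

from .model import ModelError
from .store import Store

FILE_TYPES = ("BAM", "BAMCOV", "BIGWIG", "BIGBED")
_EXT = {"BAM": ["bam"], "BAMCOV": ["bam", "bam.bw"], "BIGWIG": ["bw"],
        "BIGBED": ["bb"]}


@dataclass(frozen=True)
class DataFileRecord:
    species: str
    assembly: str
    analysis: str
    name: str
    file_type: str
    versioned: bool = False
    version: Optional[int] = None

    def __post_init__(self):
        if self.file_type not in FILE_TYPES:
            raise ModelError(f"unsupported data file type {self.file_type!r}")
        if self.versioned and self.version is None:
            raise ModelError("versioned data files need a version number")


def datafiles_path(record: DataFileRecord, root: str) -> list[str]:
    """POSIX path(s) for a record: root/species/assembly/analysis/name[.vN].ext
    (two paths for BAMCOV: the BAM and its BigWig coverage)."""
    stem = record.name
    if record.versioned:
        stem = f"{stem}.v{record.version}"
    base = posixpath.join(root, record.species, record.assembly,
                          record.analysis, stem)
    return [f"{base}.{ext}" for ext in _EXT[record.file_type]]


def store_data_file(store: Store, record: DataFileRecord) -> int:
    cur = store.execute(
        "INSERT INTO data_file(species, assembly, analysis, name, file_type, "
        "versioned, version) VALUES (?,?,?,?,?,?,?)",
        (record.species, record.assembly, record.analysis, record.name,
         record.file_type, int(record.versioned), record.version))
    store.commit()
    return cur.lastrowid


def fetch_data_files(store: Store) -> list[DataFileRecord]:
    return [DataFileRecord(r["species"], r["assembly"], r["analysis"],
                           r["name"], r["file_type"], bool(r["versioned"]),
                           r["version"])
            for r in store.execute(
                "SELECT * FROM data_file ORDER BY data_file_id")]
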