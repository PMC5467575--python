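"""Plain TSV interchange: assembly exceptions, alignment segments,
stable-id events, xrefs and fixture truth tables."""

from __future__ import annotations

import csv
from typing import Iterable

from ..altloci import AssemblyException
from ..liftover import MappingRow
from ..model import ModelError
from ..store import Store
from ..xref import Xref

EXCEPTION_COLUMNS = ("exc_type", "exc_region", "exc_start", "exc_end",
                     "ref_region", "ref_start", "ref_end")


def write_exceptions(path, exceptions: Iterable[AssemblyException]) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EXCEPTION_COLUMNS)
        for e in exceptions:
            w.writerow((e.exc_type, e.exc_region.name, e.exc_start, e.exc_end,
                        e.ref_region.name, e.ref_start, e.ref_end))
            n += 1
    return n


def read_exceptions(path, store: Store, cs) -> list[AssemblyException]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != EXCEPTION_COLUMNS:
            raise ModelError(f"unexpected exception-table header: {header}")
        for row in reader:
            out.append(AssemblyException(
                exc_type=row[0], exc_region=store.region(row[1], cs),
                exc_start=int(row[2]), exc_end=int(row[3]),
                ref_region=store.region(row[4], cs),
                ref_start=int(row[5]), ref_end=int(row[6])))
    return out


ALIGNMENT_COLUMNS = ("old_region", "old_start", "old_end", "new_region",
                     "new_start", "new_end", "ori")


def read_alignment_segments(path) -> list[MappingRow]:
    """7-column TSV of externally aligned old/new ranges."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0] == "old_region" or row[0].startswith("#"):
                continue
            out.append(MappingRow(row[0], int(row[1]), int(row[2]), row[3],
                                  int(row[4]), int(row[5]), int(row[6])))
    return out


def write_alignment_segments(path, rows: Iterable[MappingRow]) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ALIGNMENT_COLUMNS)
        for r in rows:
            w.writerow((r.old_name, r.old_start, r.old_end, r.new_name,
                        r.new_start, r.new_end, r.ori))
            n += 1
    return n


EVENT_COLUMNS = ("session", "object_type", "old_stable_id", "old_version",
                 "new_stable_id", "new_version", "score")


def write_events(path, store: Store) -> int:
    rows = store.execute(
        "SELECT * FROM stable_id_event ORDER BY mapping_session_id, "
        "object_type, IFNULL(old_stable_id,''), IFNULL(new_stable_id,'')"
    ).fetchall()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for r in rows:
            score = "" if r["score"] is None else f"{r['score']:.6f}"
            w.writerow((r["mapping_session_id"], r["object_type"],
                        r["old_stable_id"] or "", r["old_version"] or "",
                        r["new_stable_id"] or "", r["new_version"] or "",
                        score))
    return len(rows)


XREF_COLUMNS = ("source", "accession", "display_label", "info_type",
                "object_type", "object_stable_id", "query_identity",
                "target_identity", "cigar", "evidence_code")


def write_xrefs(path, xrefs: Iterable[Xref]) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(XREF_COLUMNS)
        for x in sorted(xrefs, key=lambda x: (x.source, x.accession,
                                              x.object_id)):
            w.writerow((x.source, x.accession, x.display_label, x.info_type,
                        x.object_type, x.object_id,
                        "" if x.query_identity is None else f"{x.query_identity:.2f}",
                        "" if x.target_identity is None else f"{x.target_identity:.2f}",
                        x.cigar or "", x.evidence_code or ""))
            n += 1
    return n


def read_direct_links(path) -> list[tuple[str, str, str]]:
    """2-column (accession, stable_id) TSV with an optional label column."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            label = row[2] if len(row) > 2 else row[0]
            out.append((row[0], row[1], label))
    return out


TRUTH_COLUMNS = ("object_type", "old_id", "fate", "new_id")


def write_truth(path, rows: Iterable[tuple]) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for r in rows:
            w.writerow(r)
            n += 1
    return n


def read_truth(path) -> list[tuple]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            out.append(tuple(row))
    return out
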