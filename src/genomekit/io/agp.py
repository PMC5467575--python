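"""AGP v2.0 reader/writer for assembly component maps.

Component rows (types A/D/F/G/O/P/W) become assembly segments; gap rows
(N/U) produce no segment — a gap is simply an unassembled hole in the
object's coordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from ..model import AssemblySegment, ModelError
from ..store import Store

COMPONENT_TYPES = set("ADFGOPW")
GAP_TYPES = set("NU")


@dataclass(frozen=True)
class AgpComponent:
    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str
    component_id: str
    component_beg: int
    component_end: int
    orientation: int  # +1 / -1


@dataclass(frozen=True)
class AgpGap:
    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str
    gap_length: int
    gap_type: str
    linkage: str
    linkage_evidence: str


AgpRow = Union[AgpComponent, AgpGap]


def read_agp(path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ModelError(f"{path}:{lineno}: AGP rows have 9 columns")
            obj, beg, end, part, ctype = cols[0], int(cols[1]), int(cols[2]), \
                int(cols[3]), cols[4]
            if ctype in GAP_TYPES:
                rows.append(AgpGap(obj, beg, end, part, ctype, int(cols[5]),
                                   cols[6], cols[7], cols[8]))
            elif ctype in COMPONENT_TYPES:
                ori_txt = cols[8]
                if ori_txt in ("+", "?", "0", "na"):
                    ori = 1
                elif ori_txt == "-":
                    ori = -1
                else:
                    raise ModelError(
                        f"{path}:{lineno}: bad orientation {ori_txt!r}")
                rows.append(AgpComponent(obj, beg, end, part, ctype, cols[5],
                                         int(cols[6]), int(cols[7]), ori))
            else:
                raise ModelError(
                    f"{path}:{lineno}: unknown component type {ctype!r}")
    return rows


def segments_from_agp(store: Store, rows: list[AgpRow], asm_cs,
                      cmp_cs) -> list[AssemblySegment]:
    """Resolve component rows against stored regions (gap rows are skipped)."""
    segments = []
    for row in rows:
        if isinstance(row, AgpGap):
            continue
        segments.append(AssemblySegment(
            asm_region=store.region(row.object, asm_cs),
            asm_start=row.object_beg, asm_end=row.object_end,
            cmp_region=store.region(row.component_id, cmp_cs),
            cmp_start=row.component_beg, cmp_end=row.component_end,
            ori=row.orientation))
    return segments


def write_agp(path, store: Store, asm_cs, cmp_cs,
              gap_type: str = "scaffold",
              linkage_evidence: str = "paired-ends") -> int:
    """Serialise the assembly rows between two coordinate systems.

    Holes between consecutive components (and trailing holes up to the
    object length) are written as N gap rows of the observed length.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for region in store.regions(asm_cs):
            segs = [s for s in store.assembly_segments(asm_region=region)
                    if s.cmp_region.coord_system.internal_id == cmp_cs.internal_id]
            segs.sort(key=lambda s: s.asm_start)
            part = 0
            cursor = 1
            for seg in segs:
                if seg.asm_start > cursor:
                    part += 1
                    fh.write("\t".join(map(str, (
                        region.name, cursor, seg.asm_start - 1, part, "N",
                        seg.asm_start - cursor, gap_type, "yes",
                        linkage_evidence))) + "\n")
                part += 1
                fh.write("\t".join(map(str, (
                    region.name, seg.asm_start, seg.asm_end, part, "W",
                    seg.cmp_region.name, seg.cmp_start, seg.cmp_end,
                    "+" if seg.ori == 1 else "-"))) + "\n")
                n += 1
                cursor = seg.asm_end + 1
            if segs and cursor <= region.length:
                part += 1
                fh.write("\t".join(map(str, (
                    region.name, cursor, region.length, part, "N",
                    region.length - cursor + 1, gap_type, "yes",
                    linkage_evidence))) + "\n")
    return n


def load_assembly(store: Store, agp_path, sequences: dict[str, str],
                  asm_cs, cmp_cs,
                  object_lengths: Optional[dict[str, int]] = None) -> int:
    """Register components + objects from an AGP file and component FASTA.

    Object lengths default to the maximal object_end seen in the file.
    """
    rows = read_agp(agp_path)
    lengths: dict[str, int] = dict(object_lengths or {})
    for row in rows:
        lengths[row.object] = max(lengths.get(row.object, 0), row.object_end)
    known = {r.name for r in store.regions(asm_cs)}
    for name, length in sorted(lengths.items()):
        if name not in known:
            store.add_seq_region(name, asm_cs, length)
    known_cmp = {r.name for r in store.regions(cmp_cs)}
    for row in rows:
        if isinstance(row, AgpGap) or row.component_id in known_cmp:
            continue
        seq = sequences.get(row.component_id)
        if seq is None:
            raise ModelError(
                f"component {row.component_id!r} has no FASTA sequence")
        store.add_seq_region(row.component_id, cmp_cs, len(seq), sequence=seq)
        known_cmp.add(row.component_id)
    return store.register_assembly(segments_from_agp(store, rows, asm_cs, cmp_cs))
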