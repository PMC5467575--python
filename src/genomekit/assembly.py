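"""Coordinate projection between coordinate systems and sequence assembly.

``project`` reports where the bases of a slice land in a target coordinate
system; ``transform`` rewrites a feature into target coordinates when (and
only when) the projection is one contiguous, length-preserving segment.
Multi-hop projection composes pairwise mappings along the shortest path in
the graph of coordinate-system pairs that share assembly rows.
"""

from __future__ import annotations

from collections import deque
from typing import Optional

from Bio.Seq import Seq

from .model import CoordSystem, Feature, ModelError, ProjectionSegment, Slice
from .store import Store

GAP_CHAR = "N"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _cs_graph(store: Store, species_id: int) -> dict[int, set[int]]:
    """Undirected adjacency over coord-system ids linked by assembly rows."""
    graph: dict[int, set[int]] = {}
    for row in store.execute(
            "SELECT DISTINCT a.coord_system_id AS acs, c.coord_system_id AS ccs "
            "FROM assembly "
            "JOIN seq_region a ON a.seq_region_id = assembly.asm_seq_region_id "
            "JOIN seq_region c ON c.seq_region_id = assembly.cmp_seq_region_id"):
        acs, ccs = row["acs"], row["ccs"]
        if store.coord_system_by_id(acs).species_id != species_id:
            continue
        graph.setdefault(acs, set()).add(ccs)
        graph.setdefault(ccs, set()).add(acs)
    return graph


def _mapping_path(store: Store, source: CoordSystem,
                  target: CoordSystem) -> Optional[list[int]]:
    graph = _cs_graph(store, source.species_id)
    src, dst = source.internal_id, target.internal_id
    if src == dst:
        return [src]
    if src not in graph:
        return None
    seen = {src}
    queue = deque([[src]])
    while queue:
        path = queue.popleft()
        for nxt in sorted(graph.get(path[-1], ())):
            if nxt in seen:
                continue
            if nxt == dst:
                return path + [nxt]
            seen.add(nxt)
            queue.append(path + [nxt])
    return None


def _hop(store: Store, slc: Slice, next_cs_id: int) -> list[ProjectionSegment]:
    """Project one mapping hop; segments carry offsets along the query slice."""
    rid = slc.region.internal_id
    out: list[ProjectionSegment] = []
    # downward rows: this region is the assembled side
    rows = store.execute(
        "SELECT assembly.* FROM assembly "
        "JOIN seq_region c ON c.seq_region_id = assembly.cmp_seq_region_id "
        "WHERE asm_seq_region_id=? AND c.coord_system_id=? "
        "AND asm_end>=? AND asm_start<=? ORDER BY asm_start",
        (rid, next_cs_id, slc.start, slc.end)).fetchall()
    for r in rows:
        ov_s = max(slc.start, r["asm_start"])
        ov_e = min(slc.end, r["asm_end"])
        if r["ori"] == 1:
            c_s = r["cmp_start"] + (ov_s - r["asm_start"])
            c_e = r["cmp_start"] + (ov_e - r["asm_start"])
        else:
            c_e = r["cmp_end"] - (ov_s - r["asm_start"])
            c_s = r["cmp_end"] - (ov_e - r["asm_start"])
        out.append(_segment(store, slc, ov_s, ov_e,
                            r["cmp_seq_region_id"], c_s, c_e, r["ori"]))
    # upward rows: this region is the component side
    rows = store.execute(
        "SELECT assembly.* FROM assembly "
        "JOIN seq_region a ON a.seq_region_id = assembly.asm_seq_region_id "
        "WHERE cmp_seq_region_id=? AND a.coord_system_id=? "
        "AND cmp_end>=? AND cmp_start<=? ORDER BY cmp_start",
        (rid, next_cs_id, slc.start, slc.end)).fetchall()
    for r in rows:
        ov_s = max(slc.start, r["cmp_start"])
        ov_e = min(slc.end, r["cmp_end"])
        if r["ori"] == 1:
            a_s = r["asm_start"] + (ov_s - r["cmp_start"])
            a_e = r["asm_start"] + (ov_e - r["cmp_start"])
        else:
            a_e = r["asm_end"] - (ov_s - r["cmp_start"])
            a_s = r["asm_end"] - (ov_e - r["cmp_start"])
        out.append(_segment(store, slc, ov_s, ov_e,
                            r["asm_seq_region_id"], a_s, a_e, r["ori"]))
    out.sort(key=lambda seg: seg.src_start)
    return out


def _segment(store: Store, slc: Slice, ov_s: int, ov_e: int,
             target_rid: int, t_s: int, t_e: int, ori: int) -> ProjectionSegment:
    if slc.strand == 1:
        src_s = ov_s - slc.start + 1
        src_e = ov_e - slc.start + 1
    else:
        src_s = slc.end - ov_e + 1
        src_e = slc.end - ov_s + 1
    target = Slice(store.region_by_id(target_rid), t_s, t_e, slc.strand * ori)
    return ProjectionSegment(src_s, src_e, target)


def project(store: Store, slc: Slice, target_cs: CoordSystem) -> list[ProjectionSegment]:
    """Project a slice into ``target_cs``.

    Returns the mapped pieces in ascending slice order; unmapped gaps are
    simply absent.  An empty list means no mapping path or no overlap, not
    an error.
    """
    if target_cs.internal_id is None:
        raise ModelError(f"unknown coordinate system {target_cs.name!r}")
    if slc.wraps_origin:
        raise ModelError("origin-wrapping slices cannot be projected directly; "
                         "split at the origin first")
    source_cs = slc.region.coord_system
    if source_cs.internal_id == target_cs.internal_id:
        return [ProjectionSegment(1, len(slc), slc)]
    path = _mapping_path(store, source_cs, target_cs)
    if path is None:
        return []
    segments = [ProjectionSegment(1, len(slc), slc)]
    for next_cs_id in path[1:]:
        composed: list[ProjectionSegment] = []
        for seg in segments:
            for sub in _hop(store, seg.target, next_cs_id):
                composed.append(ProjectionSegment(
                    seg.src_start + sub.src_start - 1,
                    seg.src_start + sub.src_end - 1,
                    sub.target))
        composed.sort(key=lambda s: s.src_start)
        segments = composed
    return segments


def transform(store: Store, feature: Feature,
              target_cs: CoordSystem) -> Optional[Feature]:
    """Rewrite a feature into target coordinates, or None.

    Succeeds only when the feature projects to a single contiguous segment
    on one target region covering its full length; a feature spanning a
    component junction or a mapping gap returns None (the in-band failure
    value).
    """
    if feature.wraps_origin:
        return None
    segments = project(store, feature.slice(), target_cs)
    if len(segments) != 1:
        return None
    seg = segments[0]
    if seg.src_end - seg.src_start + 1 != len(feature):
        return None
    t = seg.target
    return Feature(
        feature_type=feature.feature_type, region=t.region,
        start=t.start, end=t.end, strand=t.strand,
        analysis=feature.analysis, attributes=dict(feature.attributes),
        stable_id=feature.stable_id, version=feature.version)


def _forward_sequence(store: Store, region, start: int, end: int) -> str:
    """Plus-strand sequence for a non-wrapping range, gap-filled with N."""
    direct = store.sequence(region)
    if direct is not None:
        return direct[start - 1:end]
    seqlevel = store.sequence_level_cs(region.coord_system.species_id)
    buf = [GAP_CHAR] * (end - start + 1)
    for seg in project(store, Slice(region, start, end, 1), seqlevel):
        t = seg.target
        comp = store.sequence(t.region)
        if comp is None:
            continue
        piece = comp[t.start - 1:t.end]
        if t.strand == -1:
            piece = revcomp(piece)
        buf[seg.src_start - 1:seg.src_end] = piece
    return "".join(buf)


def _apply_masking(store: Store, region, start: int, end: int,
                   seq: str, masking: str) -> str:
    from .features import fetch_overlapping  # deferred: features imports assembly

    buf = list(seq)
    for rep in fetch_overlapping(store, Slice(region, start, end, 1), "repeat"):
        parts = [(rep.start, rep.end)] if not rep.wraps_origin else \
            [(rep.start, region.length), (1, rep.end)]
        for (rs, re_) in parts:
            lo = max(rs, start) - start
            hi = min(re_, end) - start
            for i in range(lo, hi + 1):
                if 0 <= i < len(buf):
                    buf[i] = buf[i].lower() if masking == "soft" else GAP_CHAR
    return "".join(buf)


def fetch_sequence(store: Store, slc: Slice, masking: str = "none") -> str:
    """DNA of a slice: assembled from sequence-level components, gaps as 'N',
    reverse-complemented for minus-strand slices; ``soft`` masking lowercases
    and ``hard`` masking N-replaces stored repeat features."""
    if masking not in ("none", "soft", "hard"):
        raise ModelError(f"unknown masking mode {masking!r}")
    region = slc.region
    if slc.wraps_origin:
        parts = [(slc.start, region.length), (1, slc.end)]
    else:
        parts = [(slc.start, slc.end)]
    chunks = []
    for (s, e) in parts:
        seq = _forward_sequence(store, region, s, e)
        if masking != "none":
            seq = _apply_masking(store, region, s, e, seq, masking)
        chunks.append(seq)
    out = "".join(chunks)
    if slc.strand == -1:
        out = revcomp(out)
    return out
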