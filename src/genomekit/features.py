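"""Feature persistence and the bounded-window range query.

Feature rows are indexed by (feature type, sequence region, start).  For a
query over [s, e] the store keeps, per feature type and coordinate system,
the maximum feature length m ever stored (the ``meta_coord`` bound): every
feature overlapping [s, e] must then have its start in [s - m, e], so one
index scan over that window plus an end >= s post-filter returns exactly the
overlapping set.  On circular regions the window is taken modulo the region
length, issuing up to two index scans, and origin-wrapping queries are
decomposed into two sub-queries whose union is deduplicated.
"""

from __future__ import annotations

from .model import FEATURE_TYPES, Feature, ModelError, Slice, overlaps_circular
from .store import Store


def store_feature(store: Store, f: Feature) -> int:
    """Persist a feature (toplevel regions only); returns its internal id.

    Raises on non-toplevel regions (advising projection first) and on
    coordinate violations; raises the meta_coord maximum length when the new
    feature exceeds it (the bound is never lowered).
    """
    return store.add_feature(f)


def _scan(store: Store, feature_type: str, region_id: int,
          lo: int, hi: int) -> list:
    return store.execute(
        "SELECT * FROM feature WHERE feature_type=? AND seq_region_id=? "
        "AND seq_region_start BETWEEN ? AND ? "
        "ORDER BY seq_region_start, feature_id",
        (feature_type, region_id, lo, hi)).fetchall()


def fetch_overlapping(store: Store, slc: Slice, feature_type: str,
                      slice_relative: bool = False) -> list[Feature]:
    """All stored features of ``feature_type`` overlapping the slice.

    Results are ordered by (start, internal id).  Requires a non-wrapping
    slice; use :func:`fetch_overlapping_circular` for origin-spanning
    queries on circular regions.
    """
    if feature_type not in FEATURE_TYPES:
        raise ModelError(f"unknown feature type {feature_type!r}")
    if slc.wraps_origin:
        raise ModelError("origin-spanning slice: use fetch_overlapping_circular")
    region = slc.region
    s, e = slc.start, slc.end
    m = store.max_feature_length(feature_type, region.coord_system)
    window_lo = 1 if m is None else s - m
    rows = list(_scan(store, feature_type, region.internal_id,
                      max(1, window_lo), e))
    if region.is_circular and window_lo < 1:
        # window wraps behind the origin: scan the tail of the region too
        rows += _scan(store, feature_type, region.internal_id,
                      region.length + window_lo, region.length)
    out: list[Feature] = []
    seen: set[int] = set()
    for row in rows:
        if row["feature_id"] in seen:
            continue
        if region.is_circular:
            if not overlaps_circular(row["seq_region_start"], row["seq_region_end"],
                                     s, e, region.length):
                continue
        elif row["seq_region_end"] < s:
            continue
        seen.add(row["feature_id"])
        out.append(store.feature_from_row(row))
    out.sort(key=lambda f: (f.start, f.internal_id))
    if slice_relative:
        out = [to_slice_relative(f, slc) for f in out]
    return out


def fetch_overlapping_circular(store: Store, slc: Slice,
                               feature_type: str) -> list[Feature]:
    """Origin-spanning query on a circular region, as two sub-queries.

    The first runs from the requested start to the region length, the second
    from position 1 to the requested end; features appearing in both (those
    that themselves pass through the origin) are returned once.
    """
    region = slc.region
    if not region.is_circular:
        raise ModelError(
            f"region {region.name!r} is linear; origin-spanning queries apply "
            f"to circular regions only")
    if not slc.wraps_origin:
        raise ModelError("slice does not span the origin (start <= end)")
    first = fetch_overlapping(
        store, Slice(region, slc.start, region.length, slc.strand), feature_type)
    second = fetch_overlapping(
        store, Slice(region, 1, slc.end, slc.strand), feature_type)
    seen: set[int] = set()
    out: list[Feature] = []
    for f in first + second:
        if f.internal_id in seen:
            continue
        seen.add(f.internal_id)
        out.append(f)
    out.sort(key=lambda f: (f.start, f.internal_id))
    return out


def to_slice_relative(f: Feature, slc: Slice) -> Feature:
    """Re-express feature coordinates relative to a slice.

    relative = absolute - slice.start + 1 on the plus strand; on a minus
    strand slice positions count from the slice end and strands multiply.
    Relative coordinates may fall outside [1, len(slice)] for features
    extending past the slice; that is intentional (no clipping).
    """
    if slc.strand == 1:
        rs = f.start - slc.start + 1
        re_ = f.end - slc.start + 1
    else:
        rs = slc.end - f.end + 1
        re_ = slc.end - f.start + 1
    g = Feature.__new__(Feature)
    g.feature_type = f.feature_type
    g.region = f.region
    g.start = rs
    g.end = re_
    g.strand = f.strand * slc.strand
    g.analysis = f.analysis
    g.attributes = dict(f.attributes)
    g.stable_id = f.stable_id
    g.version = f.version
    g.internal_id = f.internal_id
    return g
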