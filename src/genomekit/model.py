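"""Core domain objects for the annotation store.

Coordinates are 1-based and fully closed everywhere in the model; only the
UCSC chain writer converts to 0-based half-open on output.  Strand is encoded
as +1/-1; unstranded features are stored on +1 with an attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = (1, -1)

FEATURE_TYPES = ("gene", "transcript", "exon", "simple", "repeat")


class ModelError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class CoordSystem:
    """A named, ranked level of an assembly (chromosome, scaffold, contig...).

    ``rank`` 1 is the highest level.  At most one coordinate system per
    species actually carries DNA sequence (``is_sequence_level``).
    """

    name: str
    version: Optional[str] = None
    rank: int = 1
    species_id: int = 1
    is_sequence_level: bool = False
    is_default: bool = True
    internal_id: Optional[int] = None

    def __post_init__(self):
        if self.rank < 1:
            raise ModelError(f"coord system rank must be >= 1, got {self.rank}")
        if self.species_id < 1:
            raise ModelError("species_id must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.name, self.version, self.species_id)


@dataclass(frozen=True)
class SeqRegion:
    """A named sequence entity (a chromosome, a contig) in one coordinate system."""

    name: str
    coord_system: CoordSystem
    length: int
    is_circular: bool = False
    is_toplevel: bool = False
    internal_id: Optional[int] = None

    def __post_init__(self):
        if self.length < 1:
            raise ModelError(f"region length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class Slice:
    """A start-end-strand viewport onto a sequence region.

    On circular regions a slice with start > end spans the origin of
    replication; on linear regions that is an error.
    """

    region: SeqRegion
    start: int
    end: int
    strand: int = 1

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ModelError(f"strand must be +1 or -1, got {self.strand}")
        if self.start < 1:
            raise ModelError(f"slice start must be >= 1, got {self.start}")
        if self.end > self.region.length and not self.region.is_circular:
            raise ModelError(
                f"slice end {self.end} beyond region length {self.region.length}"
            )
        if self.start > self.end and not self.region.is_circular:
            raise ModelError(
                f"slice start {self.start} > end {self.end} on linear region "
                f"{self.region.name}"
            )

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def __len__(self) -> int:
        if self.wraps_origin:
            return self.region.length - self.start + 1 + self.end
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        return f"{self.region.name}:{self.start}-{self.end}:{self.strand:+d}"


@dataclass(frozen=True)
class AssemblySegment:
    """One ungapped row of the assembly hierarchy: an assembled-region range
    built from (or mapped to) a component-region range, with orientation."""

    asm_region: SeqRegion
    asm_start: int
    asm_end: int
    cmp_region: SeqRegion
    cmp_start: int
    cmp_end: int
    ori: int = 1

    def __post_init__(self):
        if self.ori not in STRANDS:
            raise ModelError(f"ori must be +1 or -1, got {self.ori}")
        if self.asm_start > self.asm_end or self.cmp_start > self.cmp_end:
            raise ModelError("segment start must not exceed end")
        if self.asm_start < 1 or self.cmp_start < 1:
            raise ModelError("segment coordinates are 1-based")
        if (self.asm_end - self.asm_start) != (self.cmp_end - self.cmp_start):
            raise ModelError(
                f"assembled and component ranges differ in length: "
                f"{self.asm_region.name}:{self.asm_start}-{self.asm_end} vs "
                f"{self.cmp_region.name}:{self.cmp_start}-{self.cmp_end}"
            )

    def __len__(self) -> int:
        return self.asm_end - self.asm_start + 1


@dataclass(frozen=True)
class ProjectionSegment:
    """A contiguous mapped piece of a projected slice.

    ``src_start``/``src_end`` are 1-based offsets along the query slice (in
    the slice's own orientation); ``target`` locates the same bases in the
    target coordinate system.
    """

    src_start: int
    src_end: int
    target: Slice

    def __post_init__(self):
        if self.src_start > self.src_end or self.src_start < 1:
            raise ModelError("invalid projection source range")
        if self.src_end - self.src_start + 1 != len(self.target):
            raise ModelError("projection source and target lengths differ")


@dataclass
class Feature:
    """A located annotation on a sequence region.

    Wrapped circular features (start > end on a circular region) pass
    through the origin exactly once; their length is
    ``region.length - start + 1 + end``.
    """

    feature_type: str
    region: SeqRegion
    start: int
    end: int
    strand: int = 1
    analysis: str = "manual"
    attributes: dict = field(default_factory=dict)
    stable_id: Optional[str] = None
    version: Optional[int] = None
    internal_id: Optional[int] = None

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise ModelError(f"unknown feature type {self.feature_type!r}")
        if self.strand not in STRANDS:
            raise ModelError(f"strand must be +1 or -1, got {self.strand}")
        if self.start < 1:
            raise ModelError("feature start must be >= 1")
        if self.end > self.region.length:
            raise ModelError(
                f"feature end {self.end} beyond region length {self.region.length}"
            )
        if self.start > self.end and not self.region.is_circular:
            raise ModelError(
                f"feature start {self.start} > end {self.end} on linear region"
            )

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def __len__(self) -> int:
        if self.wraps_origin:
            return self.region.length - self.start + 1 + self.end
        return self.end - self.start + 1

    def slice(self) -> Slice:
        return Slice(self.region, self.start, self.end, self.strand)


def feature_length(start: int, end: int, region_length: int) -> int:
    """Length of a possibly origin-wrapping feature."""
    if start > end:
        return region_length - start + 1 + end
    return end - start + 1


def overlaps_circular(f_start: int, f_end: int, s: int, e: int, region_length: int) -> bool:
    """Overlap test aware of origin-wrapping on either the feature or the query."""

    def unroll(a, b):
        # return list of linear intervals covered on [1, L]
        if a <= b:
            return [(a, b)]
        return [(a, region_length), (1, b)]

    for fa, fb in unroll(f_start, f_end):
        for qa, qb in unroll(s, e):
            if fa <= qb and fb >= qa:
                return True
    return False
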