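"""Cross-version assembly mapping and UCSC chain export.

The old-to-new mapping is seeded by shared contigs: contigs are identified
by versioned INSDC accession when available, otherwise by MD5 checksum of
the uppercased sequence (also testing the reverse complement, which flips
orientation).  Neighbouring contigs with conserved order and orientation —
exact abutment on both chromosomes — collapse into single chromosome-level
segments; remaining gaps can be filled from externally computed alignments
supplied as tabular segments.  The result is stored in the regular assembly
table (so ``project``/``transform`` work across versions unchanged) and can
be exported as a UCSC chain file for liftover tools.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional

from .assembly import revcomp
from .model import AssemblySegment, ModelError, SeqRegion
from .store import Store, StoreError


@dataclass(frozen=True)
class ContigIdentity:
    accession: Optional[str]
    md5: str  # of the uppercased sequence


@dataclass(frozen=True)
class ContigPair:
    old_region: SeqRegion
    new_region: SeqRegion
    ori: int


@dataclass(frozen=True)
class MappingRow:
    """One ungapped old->new segment, store-independent (names only)."""
    old_name: str
    old_start: int
    old_end: int
    new_name: str
    new_start: int
    new_end: int
    ori: int

    def __post_init__(self):
        if (self.old_end - self.old_start) != (self.new_end - self.new_start):
            raise ModelError(
                f"mapping row length mismatch: {self.old_name}:{self.old_start}-"
                f"{self.old_end} vs {self.new_name}:{self.new_start}-{self.new_end}")
        if self.old_start < 1 or self.new_start < 1 or self.ori not in (1, -1):
            raise ModelError("invalid mapping row")

    def __len__(self):
        return self.old_end - self.old_start + 1


def contig_identity(store: Store, region: SeqRegion) -> ContigIdentity:
    seq = store.sequence(region)
    if seq is None:
        raise StoreError(f"contig {region.name!r} has no stored sequence")
    accession = store.region_attrib(region.internal_id, "accession")
    return ContigIdentity(accession=accession,
                          md5=hashlib.md5(seq.upper().encode()).hexdigest())


def match_contigs(old_store: Store, new_store: Store) -> list[ContigPair]:
    """Pair shared contigs between two assembly versions.

    Versioned accessions take precedence; otherwise sequences are matched by
    MD5 (forward, then reverse complement giving orientation -1).  Each
    contig pairs at most once.
    """
    def inventory(store):
        cs = store.sequence_level_cs()
        entries = []
        for region in store.regions(cs):
            seq = store.sequence(region)
            ident = contig_identity(store, region)
            entries.append((region, ident, seq))
        return entries

    old_entries = inventory(old_store)
    new_entries = inventory(new_store)

    def md5_index(entries):
        idx: dict[str, list] = {}
        for region, ident, seq in entries:
            if ident.md5 in idx and idx[ident.md5][0][2].upper() != seq.upper():
                raise StoreError(
                    f"MD5 collision between distinct sequences: "
                    f"{idx[ident.md5][0][0].name!r} vs {region.name!r}")
            idx.setdefault(ident.md5, []).append((region, ident, seq))
        return idx

    new_by_md5 = md5_index(new_entries)
    md5_index(old_entries)  # collision guard on the old side too
    new_by_acc = {ident.accession: (region, ident, seq)
                  for region, ident, seq in new_entries if ident.accession}
    pairs: list[ContigPair] = []
    used_new: set[int] = set()
    for old_region, ident, seq in old_entries:
        candidate = None
        if ident.accession and ident.accession in new_by_acc:
            new_region, new_ident, new_seq = new_by_acc[ident.accession]
            if new_ident.md5 == ident.md5:
                candidate = (new_region, 1)
            elif hashlib.md5(revcomp(new_seq).upper().encode()).hexdigest() \
                    == ident.md5:
                candidate = (new_region, -1)
            else:
                raise StoreError(
                    f"accession {ident.accession!r} names different sequences "
                    f"in the two assemblies")
        else:
            for new_region, new_ident, _ in new_by_md5.get(ident.md5, ()):
                candidate = (new_region, 1)
                break
            if candidate is None:
                rc_md5 = hashlib.md5(revcomp(seq).upper().encode()).hexdigest()
                for new_region, new_ident, _ in new_by_md5.get(rc_md5, ()):
                    candidate = (new_region, -1)
                    break
        if candidate is None or candidate[0].internal_id in used_new:
            continue
        used_new.add(candidate[0].internal_id)
        pairs.append(ContigPair(old_region, candidate[0], candidate[1]))
    return pairs


def chromosome_components(store: Store, chromosome: SeqRegion) -> list[AssemblySegment]:
    """Sequence-level placements on a chromosome, in chromosome order."""
    seqlevel = store.sequence_level_cs(chromosome.coord_system.species_id)
    return [seg for seg in store.assembly_segments(asm_region=chromosome)
            if seg.cmp_region.coord_system.internal_id == seqlevel.internal_id]


def collapse_runs(old_store: Store, new_store: Store,
                  pairs: Iterable[ContigPair]) -> list[MappingRow]:
    """Chromosome-level old->new rows with conserved runs collapsed.

    A run requires exact abutment on both assemblies (a zero-length join) and
    overall orientation +1 for every member; a contig carried over with
    flipped orientation always forms its own segment.  Contigs without a
    partner contribute nothing (they are candidates for alignment fill).
    """
    pair_by_old = {p.old_region.internal_id: p for p in pairs}
    new_placement: dict[int, AssemblySegment] = {}
    for chrom in new_store.regions():
        if not chrom.is_toplevel:
            continue
        for seg in chromosome_components(new_store, chrom):
            new_placement[seg.cmp_region.internal_id] = seg
    raw: list[MappingRow] = []
    for chrom in old_store.regions():
        if not chrom.is_toplevel:
            continue
        for old_pl in chromosome_components(old_store, chrom):
            pair = pair_by_old.get(old_pl.cmp_region.internal_id)
            if pair is None:
                continue
            new_pl = new_placement.get(pair.new_region.internal_id)
            if new_pl is None:
                continue
            row = _pair_to_row(old_pl, new_pl, pair.ori)
            if row is not None:
                raw.append(row)
    raw.sort(key=lambda r: (r.old_name, r.old_start))
    return _merge_runs(raw)


def _pair_to_row(old_pl: AssemblySegment, new_pl: AssemblySegment,
                 pair_ori: int) -> Optional[MappingRow]:
    # everything below works in old-contig coordinates, then maps out to the
    # two chromosomes; partial placements contribute only their intersection
    contig_len = old_pl.cmp_region.length
    if pair_ori == 1:
        placed_lo, placed_hi = new_pl.cmp_start, new_pl.cmp_end
    else:  # new contig is the reverse complement of the old one
        placed_lo = contig_len - new_pl.cmp_end + 1
        placed_hi = contig_len - new_pl.cmp_start + 1
    lo = max(old_pl.cmp_start, placed_lo)
    hi = min(old_pl.cmp_end, placed_hi)
    if lo > hi:
        return None
    if old_pl.ori == 1:
        o_s = old_pl.asm_start + (lo - old_pl.cmp_start)
        o_e = old_pl.asm_start + (hi - old_pl.cmp_start)
    else:
        o_e = old_pl.asm_end - (lo - old_pl.cmp_start)
        o_s = old_pl.asm_end - (hi - old_pl.cmp_start)
    if pair_ori == 1:
        n_lo, n_hi = lo, hi
    else:
        n_lo = contig_len - hi + 1
        n_hi = contig_len - lo + 1
    if new_pl.ori == 1:
        ns = new_pl.asm_start + (n_lo - new_pl.cmp_start)
        ne = new_pl.asm_start + (n_hi - new_pl.cmp_start)
    else:
        ne = new_pl.asm_end - (n_lo - new_pl.cmp_start)
        ns = new_pl.asm_end - (n_hi - new_pl.cmp_start)
    ori = old_pl.ori * pair_ori * new_pl.ori
    return MappingRow(old_pl.asm_region.name, o_s, o_e,
                      new_pl.asm_region.name, ns, ne, ori)


def _merge_runs(rows: list[MappingRow]) -> list[MappingRow]:
    out: list[MappingRow] = []
    for row in rows:
        prev = out[-1] if out else None
        if (prev is not None and prev.ori == 1 and row.ori == 1
                and prev.old_name == row.old_name
                and prev.new_name == row.new_name
                and row.old_start == prev.old_end + 1
                and row.new_start == prev.new_end + 1):
            out[-1] = MappingRow(prev.old_name, prev.old_start, row.old_end,
                                 prev.new_name, prev.new_start, row.new_end, 1)
        else:
            out.append(row)
    return out


def fill_gaps(mapping: list[MappingRow],
              alignment_segments: Iterable[MappingRow]) -> list[MappingRow]:
    """Merge externally aligned segments into a contig-derived mapping.

    Each supplied segment must be internally valid and must not overlap an
    existing row on either the old or the new side.
    """
    merged = list(mapping)
    for seg in alignment_segments:
        for row in merged:
            if (row.old_name == seg.old_name
                    and seg.old_start <= row.old_end
                    and seg.old_end >= row.old_start):
                raise StoreError(
                    f"alignment segment {seg.old_name}:{seg.old_start}-"
                    f"{seg.old_end} overlaps existing mapping "
                    f"{row.old_name}:{row.old_start}-{row.old_end} (old side)")
            if (row.new_name == seg.new_name
                    and seg.new_start <= row.new_end
                    and seg.new_end >= row.new_start):
                raise StoreError(
                    f"alignment segment {seg.new_name}:{seg.new_start}-"
                    f"{seg.new_end} overlaps existing mapping "
                    f"{row.new_name}:{row.new_start}-{row.new_end} (new side)")
        merged.append(seg)
    merged.sort(key=lambda r: (r.old_name, r.old_start))
    return merged


def register_version_mapping(store: Store, rows: Iterable[MappingRow],
                             old_cs, new_cs) -> int:
    """Record mapping rows in the assembly table of a store that carries
    both assembly versions' chromosomes; projection then works unchanged."""
    segments = []
    for r in rows:
        segments.append(AssemblySegment(
            asm_region=store.region(r.old_name, old_cs),
            asm_start=r.old_start, asm_end=r.old_end,
            cmp_region=store.region(r.new_name, new_cs),
            cmp_start=r.new_start, cmp_end=r.new_end, ori=r.ori))
    return store.register_assembly(segments)


def map_position(rows: Iterable[MappingRow], name: str,
                 pos: int) -> Optional[tuple[str, int, int]]:
    """Map one old-assembly base through the rows; None when unmapped."""
    for r in rows:
        if r.old_name == name and r.old_start <= pos <= r.old_end:
            if r.ori == 1:
                return (r.new_name, r.new_start + (pos - r.old_start), 1)
            return (r.new_name, r.new_end - (pos - r.old_start), -1)
    return None


# -- UCSC chain export -----------------------------------------------------

def export_chain(rows: list[MappingRow], old_sizes: dict[str, int],
                 new_sizes: dict[str, int], ucsc_names: bool = False) -> str:
    """Serialise a mapping as UCSC chain text (old = target, new = query).

    Internal 1-based closed coordinates become 0-based half-open; chains on
    the minus strand use reverse-strand query coordinates per the chain
    spec.  The score is the sum of block sizes (liftover ignores it); chain
    ids run sequentially from 1.  ``ucsc_names`` prefixes region names with
    "chr" (chr1 rather than 1) unless already present.
    """
    if not rows:
        raise ModelError("cannot export an empty mapping")

    def pname(name: str) -> str:
        if not ucsc_names or name.startswith("chr"):
            return name
        return f"chr{name}"

    ordered = sorted(rows, key=lambda r: (r.old_name, r.old_start))
    chains: list[list[MappingRow]] = []
    for row in ordered:
        prev = chains[-1][-1] if chains else None
        collinear = (
            prev is not None and prev.old_name == row.old_name
            and prev.new_name == row.new_name and prev.ori == row.ori
            and row.old_start > prev.old_end
            and ((row.ori == 1 and row.new_start > prev.new_end)
                 or (row.ori == -1 and row.new_end < prev.new_start)))
        if collinear:
            chains[-1].append(row)
        else:
            chains.append([row])
    lines: list[str] = []
    for chain_id, chain in enumerate(chains, start=1):
        first, last = chain[0], chain[-1]
        ori = first.ori
        t_name = pname(first.old_name)
        q_name = pname(first.new_name)
        t_size = old_sizes[first.old_name]
        q_size = new_sizes[first.new_name]
        t_start, t_end = first.old_start - 1, last.old_end
        plus_lo = min(r.new_start for r in chain)
        plus_hi = max(r.new_end for r in chain)
        if ori == 1:
            q_strand, q_start, q_end = "+", plus_lo - 1, plus_hi
        else:
            q_strand = "-"
            q_start = q_size - plus_hi
            q_end = q_size - (plus_lo - 1)
        score = sum(len(r) for r in chain)
        lines.append(f"chain {score} {t_name} {t_size} + {t_start} {t_end} "
                     f"{q_name} {q_size} {q_strand} {q_start} {q_end} {chain_id}")
        for row, nxt in zip(chain, chain[1:]):
            dt = nxt.old_start - row.old_end - 1
            dq = (nxt.new_start - row.new_end - 1 if ori == 1
                  else row.new_start - nxt.new_end - 1)
            lines.append(f"{len(row)} {dt} {dq}")
        lines.append(f"{len(last)}")
        lines.append("")
    return "\n".join(lines) + "\n"
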