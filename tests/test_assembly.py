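"""Projection, transformation and sequence retrieval."""

import numpy as np
import pytest

from genomekit import assembly
from genomekit.model import (AssemblySegment, CoordSystem, Feature,
                             ModelError, Slice)
from genomekit.store import Store, StoreError
from genomekit.synthetic import random_dna, rng_for


def test_register_identity_tiling_counts(tiling_store):
    rows = tiling_store.assembly_segments()
    assert len(rows) == 2


def test_register_empty_list_is_noop(tiling_store):
    before = {r.name: r.is_toplevel for r in tiling_store.regions()}
    assert tiling_store.register_assembly([]) == 0
    after = {r.name: r.is_toplevel for r in tiling_store.regions()}
    assert before == after


def test_overlapping_asm_rows_rejected_naming_pair(tiling_store):
    chrom_cs = tiling_store.coord_system("chromosome", "ASM1")
    contig_cs = tiling_store.sequence_level_cs()
    chrom = tiling_store.region("1", chrom_cs)
    c = tiling_store.add_seq_region("C", contig_cs, 20, sequence="A" * 20)
    with pytest.raises(StoreError, match="overlap"):
        tiling_store.register_assembly(
            [AssemblySegment(chrom, 50, 69, c, 1, 20, 1)])


def test_length_mismatch_rejected(tiling_store):
    chrom_cs = tiling_store.coord_system("chromosome", "ASM1")
    chrom = tiling_store.region("1", chrom_cs)
    a = tiling_store.region("A", tiling_store.sequence_level_cs())
    with pytest.raises(ModelError, match="length"):
        AssemblySegment(chrom, 1, 10, a, 1, 5, 1)


def test_three_level_hierarchy_toplevel_flags():
    """Only the region never used as a component is toplevel."""
    store = Store()
    store.add_species("x")
    chrom_cs = store.add_coord_system(CoordSystem("chromosome", rank=1))
    scaf_cs = store.add_coord_system(CoordSystem("scaffold", rank=2))
    contig_cs = store.add_coord_system(CoordSystem("contig", rank=3,
                                                   is_sequence_level=True))
    chrom = store.add_seq_region("1", chrom_cs, 200)
    s1 = store.add_seq_region("S1", scaf_cs, 120)
    s2 = store.add_seq_region("S2", scaf_cs, 80)
    c1 = store.add_seq_region("C1", contig_cs, 120, sequence="A" * 120)
    c2 = store.add_seq_region("C2", contig_cs, 80, sequence="C" * 80)
    n = store.register_assembly([
        AssemblySegment(chrom, 1, 120, s1, 1, 120, 1),
        AssemblySegment(chrom, 121, 200, s2, 1, 80, 1),
        AssemblySegment(s1, 1, 120, c1, 1, 120, 1),
        AssemblySegment(s2, 1, 80, c2, 1, 80, 1),
    ])
    assert n == 4
    toplevel = {r.name for r in store.regions() if r.is_toplevel}
    assert toplevel == {"1"}


class TestProject:
    def test_full_tiling(self, tiling_store):
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        segs = assembly.project(tiling_store, Slice(chrom, 1, 100),
                                tiling_store.sequence_level_cs())
        assert [(s.src_start, s.src_end, s.target.region.name,
                 s.target.start, s.target.end, s.target.strand)
                for s in segs] == [(1, 60, "A", 1, 60, 1),
                                   (61, 100, "B", 1, 40, 1)]

    def test_junction_spanning_slice(self, tiling_store):
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        segs = assembly.project(tiling_store, Slice(chrom, 55, 65),
                                tiling_store.sequence_level_cs())
        assert [(s.src_start, s.src_end, s.target.region.name,
                 s.target.start, s.target.end)
                for s in segs] == [(1, 6, "A", 55, 60), (7, 11, "B", 1, 5)]

    def test_gap_only_slice_is_empty(self):
        store = Store()
        store.add_species("x")
        chrom_cs = store.add_coord_system(CoordSystem("chromosome", rank=1))
        contig_cs = store.add_coord_system(
            CoordSystem("contig", rank=2, is_sequence_level=True))
        chrom = store.add_seq_region("1", chrom_cs, 100)
        a = store.add_seq_region("A", contig_cs, 30, sequence="A" * 30)
        store.register_assembly([AssemblySegment(chrom, 1, 30, a, 1, 30, 1)])
        assert assembly.project(store, Slice(chrom, 40, 60), contig_cs) == []

    def test_unknown_coord_system_is_error(self, tiling_store):
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        with pytest.raises(ModelError):
            assembly.project(tiling_store, Slice(chrom, 1, 10),
                             CoordSystem("plasmid", rank=9))

    def test_no_mapping_path_gives_empty_list(self, tiling_store):
        other_cs = tiling_store.add_coord_system(CoordSystem("clone", rank=5))
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        assert assembly.project(tiling_store, Slice(chrom, 1, 10),
                                other_cs) == []


class TestTransform:
    def test_feature_inside_one_component(self, tiling_store):
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        f = Feature("simple", chrom, 10, 20, 1)
        g = assembly.transform(tiling_store, f,
                               tiling_store.sequence_level_cs())
        assert (g.region.name, g.start, g.end, g.strand) == ("A", 10, 20, 1)

    def test_junction_spanning_feature_is_none(self, tiling_store):
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        f = Feature("simple", chrom, 55, 65, 1)
        assert assembly.transform(tiling_store, f,
                                  tiling_store.sequence_level_cs()) is None

    def test_minus_component_flips_strand_and_coordinates(self):
        store = Store()
        store.add_species("x")
        chrom_cs = store.add_coord_system(CoordSystem("chromosome", rank=1))
        contig_cs = store.add_coord_system(
            CoordSystem("contig", rank=2, is_sequence_level=True))
        chrom = store.add_seq_region("1", chrom_cs, 50)
        c = store.add_seq_region("C", contig_cs, 50, sequence="A" * 50)
        store.register_assembly([AssemblySegment(chrom, 1, 50, c, 1, 50, -1)])
        f = Feature("simple", chrom, 10, 20, 1)
        g = assembly.transform(store, f, contig_cs)
        # reverse-complement position rule: cmp_start + (asm_end - f_end)
        assert (g.start, g.end, g.strand) == (1 + (50 - 20), 1 + (50 - 10), -1)

    def test_transform_none_iff_projection_not_single(self, tiling_store):
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        seqlevel = tiling_store.sequence_level_cs()
        for (s, e) in [(1, 5), (58, 62), (61, 99), (30, 80)]:
            f = Feature("simple", chrom, s, e, 1)
            segs = assembly.project(tiling_store, f.slice(), seqlevel)
            expected_none = (len(segs) != 1
                             or (segs[0].src_end - segs[0].src_start + 1)
                             != len(f))
            assert (assembly.transform(tiling_store, f, seqlevel) is None) \
                == expected_none


class TestFetchSequence:
    def test_seqlevel_verbatim_and_revcomp_involution(self, tiling_store):
        a = tiling_store.region("A", tiling_store.sequence_level_cs())
        fwd = assembly.fetch_sequence(tiling_store, Slice(a, 1, 10))
        assert fwd == tiling_store.sequence(a)[:10]
        rev = assembly.fetch_sequence(tiling_store, Slice(a, 1, 10, -1))
        assert assembly.revcomp(rev) == fwd

    def test_gap_filled_with_n_run(self):
        store = Store()
        store.add_species("x")
        chrom_cs = store.add_coord_system(CoordSystem("chromosome", rank=1))
        contig_cs = store.add_coord_system(
            CoordSystem("contig", rank=2, is_sequence_level=True))
        chrom = store.add_seq_region("1", chrom_cs, 100)
        a = store.add_seq_region("A", contig_cs, 30, sequence="G" * 30)
        b = store.add_seq_region("B", contig_cs, 40, sequence="C" * 40)
        store.register_assembly([AssemblySegment(chrom, 1, 30, a, 1, 30, 1),
                                 AssemblySegment(chrom, 61, 100, b, 1, 40, 1)])
        seq = assembly.fetch_sequence(store, Slice(chrom, 1, 100))
        assert seq == "G" * 30 + "N" * 30 + "C" * 40

    def test_masking_modes(self, tiling_store):
        from genomekit import features
        chrom = tiling_store.region(
            "1", tiling_store.coord_system("chromosome", "ASM1"))
        features.store_feature(
            tiling_store, Feature("repeat", chrom, 5, 8, 1))
        plain = assembly.fetch_sequence(tiling_store, Slice(chrom, 1, 10))
        soft = assembly.fetch_sequence(tiling_store, Slice(chrom, 1, 10),
                                       masking="soft")
        hard = assembly.fetch_sequence(tiling_store, Slice(chrom, 1, 10),
                                       masking="hard")
        assert soft == plain[:4] + plain[4:8].lower() + plain[8:]
        assert hard == plain[:4] + "NNNN" + plain[8:]

    def test_circular_wrap_length_contract(self):
        store = Store()
        store.add_species("x")
        cs = store.add_coord_system(
            CoordSystem("plasmid", rank=1, is_sequence_level=True))
        region = store.add_seq_region("p", cs, 20, circular=True,
                                      sequence="ACGTACGTACGTACGTACGT")
        slc = Slice(region, 18, 5)
        seq = assembly.fetch_sequence(store, slc)
        assert len(seq) == len(slc) == 8
        assert seq == "CGT" + "ACGTA"  # tail (18..20) + head (1..5)


def _random_assembly(seed):
    """A small random 3-level hierarchy for oracle comparison."""
    rng = rng_for(seed, "oracle-assembly")
    store = Store()
    store.add_species("x")
    chrom_cs = store.add_coord_system(CoordSystem("chromosome", rank=1))
    scaf_cs = store.add_coord_system(CoordSystem("scaffold", rank=2))
    contig_cs = store.add_coord_system(
        CoordSystem("contig", rank=3, is_sequence_level=True))
    chrom = store.add_seq_region("1", chrom_cs, 10_000)
    segs = []
    cursor = 1
    for i in range(int(rng.integers(2, 5))):
        length = int(rng.integers(300, 1500))
        scaf = store.add_seq_region(f"S{i}", scaf_cs, length)
        segs.append(AssemblySegment(chrom, cursor, cursor + length - 1,
                                    scaf, 1, length, int(rng.choice([1, -1]))))
        cursor += length + int(rng.integers(0, 200))
        sub_cursor = 1
        while sub_cursor <= length - 50:
            sub_len = int(rng.integers(50, 400))
            sub_end = min(sub_cursor + sub_len - 1, length)
            contig = store.add_seq_region(
                f"C{i}_{sub_cursor}", contig_cs, sub_end - sub_cursor + 1,
                sequence=random_dna(rng, sub_end - sub_cursor + 1))
            segs.append(AssemblySegment(scaf, sub_cursor, sub_end, contig, 1,
                                        sub_end - sub_cursor + 1,
                                        int(rng.choice([1, -1]))))
            sub_cursor = sub_end + 1 + int(rng.integers(0, 60))
    store.register_assembly(segs)
    return store, chrom


def _oracle_base_walk(store, region, pos, target_cs):
    """Recursive per-base mapping through the assembly rows."""
    if region.coord_system.internal_id == target_cs.internal_id:
        return (region.name, pos, 1)
    for seg in store.assembly_segments(asm_region=region):
        if seg.asm_start <= pos <= seg.asm_end:
            if seg.ori == 1:
                sub = seg.cmp_start + (pos - seg.asm_start)
            else:
                sub = seg.cmp_end - (pos - seg.asm_start)
            hit = _oracle_base_walk(store, seg.cmp_region, sub, target_cs)
            if hit is not None:
                name, p, ori = hit
                return (name, p, ori * seg.ori)
    return None


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_projection_agrees_with_per_base_oracle(seed):
    store, chrom = _random_assembly(seed)
    target_cs = store.sequence_level_cs()
    rng = np.random.default_rng(seed + 100)
    for _ in range(120):
        s = int(rng.integers(1, chrom.length - 200))
        e = s + int(rng.integers(0, 200))
        strand = int(rng.choice([1, -1]))
        slc = Slice(chrom, s, e, strand)
        got = {}
        for seg in assembly.project(store, slc, target_cs):
            t = seg.target
            for i in range(len(t)):
                off = seg.src_start + i
                abs_pos = s + off - 1 if strand == 1 else e - off + 1
                tpos = t.start + i if t.strand == 1 else t.end - i
                got[abs_pos] = (t.region.name, tpos,
                                t.strand * strand)
        for pos in range(s, e + 1):
            assert got.get(pos) == _oracle_base_walk(store, chrom, pos,
                                                     target_cs), \
                f"mismatch at {pos} (slice {s}-{e}:{strand})"


@pytest.mark.parametrize("seed", [3, 4])
def test_down_then_up_projection_round_trips(seed):
    store, chrom = _random_assembly(seed)
    seqlevel = store.sequence_level_cs()
    rng = np.random.default_rng(seed)
    for _ in range(60):
        s = int(rng.integers(1, chrom.length - 100))
        e = s + int(rng.integers(0, 100))
        slc = Slice(chrom, s, e)
        down = assembly.project(store, slc, seqlevel)
        recovered = []
        for seg in down:
            for up in assembly.project(store, seg.target,
                                       chrom.coord_system):
                t = up.target
                assert t.region.internal_id == chrom.internal_id
                recovered.append((t.start, t.end))

        def merge(ranges):
            out = []
            for lo, hi in sorted(ranges):
                if out and lo == out[-1][1] + 1:
                    out[-1] = (out[-1][0], hi)
                else:
                    out.append((lo, hi))
            return out

        # re-projecting every mapped piece upward must reproduce exactly
        # the chromosome ranges the original slice projected down from
        covered = merge((s + seg.src_start - 1, s + seg.src_end - 1)
                        for seg in down)
        assert merge(recovered) == covered
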