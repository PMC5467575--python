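"""Cross-version mapping, run collapsing and chain-file round trips."""

import numpy as np
import pytest

from genomekit import assembly, liftover
from genomekit.model import AssemblySegment, CoordSystem, Feature, Slice
from genomekit.store import Store, StoreError
from genomekit.synthetic import random_dna, rng_for

# -- independent chain parser (test-side oracle) ---------------------------


def parse_chain(text):
    """Minimal independent UCSC chain parser: list of
    (t_name, t_size, t_start, t_end, q_name, q_size, q_strand, q_start,
    blocks) with blocks as (size, dt, dq)."""
    chains = []
    blocks = []
    header = None
    for line in text.splitlines():
        if line.startswith("chain "):
            header = line.split()
            blocks = []
        elif line.strip() == "":
            continue
        else:
            parts = [int(x) for x in line.split()]
            blocks.append(parts if len(parts) == 3 else parts + [0, 0])
            if len(parts) == 1:
                chains.append((header, blocks))
    return chains


def chain_map(chains, name, pos1):
    """Map a 1-based old-assembly position through parsed chains."""
    p0 = pos1 - 1
    for header, blocks in chains:
        (_, _, t_name, t_size, _, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, _) = header
        if t_name != name or not (int(t_start) <= p0 < int(t_end)):
            continue
        t_cursor, q_cursor = int(t_start), int(q_start)
        for size, dt, dq in blocks:
            if t_cursor <= p0 < t_cursor + size:
                q0 = q_cursor + (p0 - t_cursor)
                if q_strand == "-":
                    return (q_name, int(q_size) - q0, -1)
                return (q_name, q0 + 1, 1)
            t_cursor += size + dt
            q_cursor += size + dq
    return None


# -- fixtures --------------------------------------------------------------


def _assembly_store(version, layout, seqs):
    """layout: list of (chrom, [(contig, ori), ...]) with exact abutment."""
    store = Store()
    store.add_species("x")
    chrom_cs = store.add_coord_system(
        CoordSystem("chromosome", version=version, rank=1))
    contig_cs = store.add_coord_system(
        CoordSystem("contig", rank=2, is_sequence_level=True))
    for chrom_name, contigs in layout:
        total = sum(len(seqs[c]) for c, _ in contigs)
        chrom = store.add_seq_region(chrom_name, chrom_cs, total)
        cursor = 1
        rows = []
        for contig_name, ori in contigs:
            seq = seqs[contig_name]
            ctg = store.add_seq_region(contig_name, contig_cs, len(seq),
                                       sequence=seq)
            rows.append(AssemblySegment(chrom, cursor,
                                        cursor + len(seq) - 1, ctg, 1,
                                        len(seq), ori))
            cursor += len(seq)
        store.register_assembly(rows)
    return store


@pytest.fixture
def shared_seqs():
    rng = rng_for(42, "liftover")
    return {f"c{i}": random_dna(rng, int(rng.integers(80, 200)))
            for i in range(1, 6)}


class TestMatchContigs:
    def test_identical_accessions_pair_forward(self, shared_seqs):
        old = _assembly_store("V1", [("A", [("c1", 1)])], shared_seqs)
        new = _assembly_store("V2", [("A", [("c1", 1)])], shared_seqs)
        for s in (old, new):
            r = s.region("c1", s.sequence_level_cs())
            s.set_region_attrib(r.internal_id, "accession", "CTG1.2")
        pairs = liftover.match_contigs(old, new)
        assert [(p.old_region.name, p.new_region.name, p.ori)
                for p in pairs] == [("c1", "c1", 1)]

    def test_unversioned_contigs_pair_by_md5(self, shared_seqs):
        old = _assembly_store("V1", [("A", [("c1", 1)])], shared_seqs)
        renamed = {"cX": shared_seqs["c1"]}
        new = _assembly_store("V2", [("A", [("cX", 1)])], renamed)
        pairs = liftover.match_contigs(old, new)
        assert [(p.old_region.name, p.new_region.name, p.ori)
                for p in pairs] == [("c1", "cX", 1)]

    def test_reverse_complement_pairs_with_flipped_orientation(self, shared_seqs):
        old = _assembly_store("V1", [("A", [("c1", 1)])], shared_seqs)
        rc = {"cR": assembly.revcomp(shared_seqs["c1"])}
        new = _assembly_store("V2", [("A", [("cR", 1)])], rc)
        pairs = liftover.match_contigs(old, new)
        assert [(p.old_region.name, p.new_region.name, p.ori)
                for p in pairs] == [("c1", "cR", -1)]

    def test_accession_naming_different_sequence_is_error(self, shared_seqs):
        old = _assembly_store("V1", [("A", [("c1", 1)])], shared_seqs)
        new = _assembly_store("V2", [("A", [("c2", 1)])], shared_seqs)
        for s, name in ((old, "c1"), (new, "c2")):
            r = s.region(name, s.sequence_level_cs())
            s.set_region_attrib(r.internal_id, "accession", "CTG1.2")
        with pytest.raises(StoreError, match="accession"):
            liftover.match_contigs(old, new)


class TestCollapseRuns:
    def test_conserved_abutting_contigs_collapse_to_one(self, shared_seqs):
        layout = [("A", [("c1", 1), ("c2", 1), ("c3", 1)])]
        old = _assembly_store("V1", layout, shared_seqs)
        new = _assembly_store("V2", layout, shared_seqs)
        rows = liftover.collapse_runs(old, new,
                                      liftover.match_contigs(old, new))
        total = sum(len(shared_seqs[c]) for c in ("c1", "c2", "c3"))
        assert [(r.old_start, r.old_end, r.new_start, r.new_end, r.ori)
                for r in rows] == [(1, total, 1, total, 1)]

    def test_inverted_middle_contig_breaks_the_run(self, shared_seqs):
        old = _assembly_store("V1", [("A", [("c1", 1), ("c2", 1),
                                            ("c3", 1)])], shared_seqs)
        new_seqs = dict(shared_seqs)
        new_seqs["c2"] = assembly.revcomp(shared_seqs["c2"])
        new = _assembly_store("V2", [("A", [("c1", 1), ("c2", 1),
                                            ("c3", 1)])], new_seqs)
        rows = liftover.collapse_runs(old, new,
                                      liftover.match_contigs(old, new))
        assert len(rows) == 3
        assert [r.ori for r in rows] == [1, -1, 1]

    def test_no_shared_contigs_gives_empty_mapping(self, shared_seqs):
        old = _assembly_store("V1", [("A", [("c1", 1)])], shared_seqs)
        new = _assembly_store("V2", [("A", [("c2", 1)])], shared_seqs)
        assert liftover.collapse_runs(
            old, new, liftover.match_contigs(old, new)) == []

    def test_collapse_is_maximal(self, shared_seqs):
        """No two adjacent output rows can themselves be merged."""
        old = _assembly_store("V1", [("A", [("c1", 1), ("c2", 1)]),
                                     ("B", [("c3", 1), ("c4", 1)])],
                              shared_seqs)
        new = _assembly_store("V2", [("A", [("c1", 1), ("c2", 1),
                                            ("c3", 1), ("c4", 1)])],
                              shared_seqs)
        rows = liftover.collapse_runs(old, new,
                                      liftover.match_contigs(old, new))
        for a, b in zip(rows, rows[1:]):
            mergeable = (a.ori == b.ori == 1 and a.old_name == b.old_name
                         and a.new_name == b.new_name
                         and b.old_start == a.old_end + 1
                         and b.new_start == a.new_end + 1)
            assert not mergeable


class TestFillGaps:
    def test_fitting_segment_extends_mapping(self):
        base = [liftover.MappingRow("A", 1, 100, "A", 1, 100, 1)]
        extra = liftover.MappingRow("A", 151, 200, "A", 161, 210, 1)
        merged = liftover.fill_gaps(base, [extra])
        assert len(merged) == 2

    def test_overlapping_segment_rejected_naming_range(self):
        base = [liftover.MappingRow("A", 1, 100, "A", 1, 100, 1)]
        bad = liftover.MappingRow("A", 90, 140, "A", 200, 250, 1)
        with pytest.raises(StoreError, match="90-140"):
            liftover.fill_gaps(base, [bad])

    def test_result_sorted_by_old_side_start(self):
        base = [liftover.MappingRow("A", 500, 600, "A", 500, 600, 1)]
        extras = [liftover.MappingRow("A", 700, 750, "A", 700, 750, 1),
                  liftover.MappingRow("A", 100, 150, "A", 100, 150, 1)]
        merged = liftover.fill_gaps(base, extras)
        assert [r.old_start for r in merged] == [100, 500, 700]


class TestExportChain:
    def test_single_segment_coordinate_conversion(self):
        rows = [liftover.MappingRow("1", 1, 100, "1", 1, 100, 1)]
        text = liftover.export_chain(rows, {"1": 100}, {"1": 100})
        header = text.splitlines()[0].split()
        assert header[:11] == ["chain", "100", "1", "100", "+", "0", "100",
                               "1", "100", "+", "0"]
        assert text.splitlines()[1] == "100"

    def test_collinear_segments_encode_gap_sizes(self):
        rows = [liftover.MappingRow("1", 1, 100, "1", 1, 100, 1),
                liftover.MappingRow("1", 111, 160, "1", 101, 150, 1)]
        text = liftover.export_chain(rows, {"1": 200}, {"1": 200})
        lines = text.splitlines()
        assert lines[0].startswith("chain 150 1 200 + 0 160 1 200 + 0 150 1")
        assert lines[1] == "100 10 0"
        assert lines[2] == "50"

    def test_ucsc_name_prefixing(self):
        rows = [liftover.MappingRow("1", 1, 10, "1", 1, 10, 1)]
        text = liftover.export_chain(rows, {"1": 10}, {"1": 10},
                                     ucsc_names=True)
        fields = text.splitlines()[0].split()
        assert fields[2] == "chr1" and fields[7] == "chr1"


def _random_version_pair(seed):
    rng = rng_for(seed, "version-pair")
    seqs = {f"c{i}": random_dna(rng, int(rng.integers(100, 300)))
            for i in range(8)}
    names = list(seqs)
    old_layout = [("A", [(n, 1) for n in names[:4]]),
                  ("B", [(n, 1) for n in names[4:]])]
    # new: one contig inverted, one moved across chromosomes, one dropped
    new_seqs = dict(seqs)
    new_seqs["c2"] = assembly.revcomp(seqs["c2"])
    del new_seqs["c6"]
    new_layout = [("A", [("c0", 1), ("c1", 1), ("c2", 1), ("c7", 1)]),
                  ("B", [("c4", 1), ("c5", 1), ("c3", 1)])]
    old = _assembly_store("V1", old_layout, seqs)
    new = _assembly_store("V2", new_layout, new_seqs)
    return old, new


@pytest.mark.parametrize("seed", [0, 1])
def test_chain_round_trip_matches_direct_mapping(seed):
    old, new = _random_version_pair(seed)
    rows = liftover.collapse_runs(old, new, liftover.match_contigs(old, new))
    old_sizes = {r.name: r.length for r in old.regions() if r.is_toplevel}
    new_sizes = {r.name: r.length for r in new.regions() if r.is_toplevel}
    chains = parse_chain(liftover.export_chain(rows, old_sizes, new_sizes))
    rng = np.random.default_rng(seed)
    checked = 0
    for _ in range(500):
        name = str(rng.choice(list(old_sizes)))
        pos = int(rng.integers(1, old_sizes[name], endpoint=True))
        direct = liftover.map_position(rows, name, pos)
        via_chain = chain_map(chains, name, pos)
        if direct is None:
            assert via_chain is None
        else:
            assert via_chain == direct
            checked += 1
    assert checked > 100


def test_projection_through_registered_version_mapping():
    """project/transform work unchanged across assembly versions."""
    old, new = _random_version_pair(7)
    rows = liftover.collapse_runs(old, new, liftover.match_contigs(old, new))
    # combined store carrying both versions' chromosomes
    combo = Store()
    combo.add_species("x")
    v1 = combo.add_coord_system(CoordSystem("chromosome", version="V1",
                                            rank=1, is_default=True))
    v2 = combo.add_coord_system(CoordSystem("chromosome", version="V2",
                                            rank=3, is_default=False))
    for store, cs in ((old, v1), (new, v2)):
        for r in store.regions():
            if r.is_toplevel:
                combo.add_seq_region(r.name, cs, r.length)
    liftover.register_version_mapping(combo, rows, v1, v2)
    rng = np.random.default_rng(3)
    old_sizes = {r.name: r.length for r in old.regions() if r.is_toplevel}
    mapped = 0
    for _ in range(100):
        name = str(rng.choice(list(old_sizes)))
        s = int(rng.integers(1, old_sizes[name] - 30))
        f = Feature("simple", combo.region(name, v1), s, s + 20,
                    int(rng.choice([1, -1])))
        got = assembly.transform(combo, f, v2)
        expected = [liftover.map_position(rows, name, p)
                    for p in range(s, s + 21)]
        if got is None:
            covered = {e[0] for e in expected if e}
            contiguous = (all(expected)
                          and len(covered) == 1
                          and sorted(p for _, p, _ in expected)
                          == list(range(min(p for _, p, _ in expected),
                                        max(p for _, p, _ in expected) + 1)))
            assert not contiguous
        else:
            mapped += 1
            want = {(got.region.name, p)
                    for p in range(got.start, got.end + 1)}
            assert {(e[0], e[1]) for e in expected} == want
    assert mapped > 30
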