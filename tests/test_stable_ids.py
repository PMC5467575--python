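"""Stable-identifier mapping: thresholds, penalties, versions, history."""

import pytest

from genomekit import stable_ids as si
from genomekit.stable_ids import (AnnSet, ExonView, GeneView, TranscriptView,
                                  map_exons, map_genes, map_transcripts,
                                  run_mapping, score_transcript_pair)


def _exon(iid, sid, s, e, region="1", strand=1, seq=None, version=1):
    return ExonView(iid, sid, version, region, s, e, strand, seq)


def _annset(exons, transcripts=(), genes=()):
    out = AnnSet()
    for e in exons:
        out.exons[e.internal_id] = e
    for t in transcripts:
        out.transcripts[t.internal_id] = t
    for g in genes:
        out.genes[g.internal_id] = g
    return out


class TestExonMapping:
    def test_identical_exon_keeps_id_and_version(self):
        src = _annset([_exon(1, "E1", 100, 199, version=3)])
        tgt = _annset([_exon(11, "TMP", 100, 199)])
        out = map_exons(src, tgt)
        assert out.assignments[11][:2] == ("E1", 3)

    def test_five_base_extension_keeps_id_bumps_version(self):
        # shared 100 of 105 bases = 0.952 >= 0.90
        src = _annset([_exon(1, "E1", 100, 199, version=1)])
        tgt = _annset([_exon(11, "TMP", 100, 204)])
        out = map_exons(src, tgt)
        assert out.assignments[11][:2] == ("E1", 2)

    def test_half_overlap_gets_fresh_id_at_version_one(self):
        src = _annset([_exon(1, "E1", 100, 199)])
        tgt = _annset([_exon(11, "TMP", 150, 249)])
        out = map_exons(src, tgt)
        sid, version, _ = out.assignments[11]
        assert sid != "E1" and version == 1
        kinds = [(e.old_id, e.new_id) for e in out.events]
        assert ("E1", None) in kinds  # death of the source id

    @pytest.mark.parametrize("shared_pct,kept", [(89, False), (90, True),
                                                 (91, True)])
    def test_retention_threshold_boundary(self, shared_pct, kept):
        src = _annset([_exon(1, "E1", 1, 100)])
        tgt = _annset([_exon(11, "TMP", 1, shared_pct)])
        out = map_exons(src, tgt)
        assert (out.assignments[11][0] == "E1") == kept

    @pytest.mark.parametrize("subs,kept", [(9, True), (10, True), (11, False)])
    def test_cross_assembly_identity_threshold(self, subs, kept):
        base = ("ACGT" * 25)
        mutated = list(base)
        for i in range(subs):
            pos = i * 7
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[base[pos]]
        src = _annset([_exon(1, "E1", 1, 100, seq=base)])
        tgt = _annset([_exon(11, "TMP", 1, 100, seq="".join(mutated))])
        out = map_exons(src, tgt, same_assembly=False)
        assert (out.assignments[11][0] == "E1") == kept

    def test_each_exon_matches_at_most_once_greedy_by_fraction(self):
        src = _annset([_exon(1, "E1", 1, 100)])
        tgt = _annset([_exon(11, "TMP1", 1, 100), _exon(12, "TMP2", 1, 104)])
        out = map_exons(src, tgt)
        assert out.assignments[11][0] == "E1"     # the better fraction wins
        assert out.assignments[12][0] != "E1"


def _simple_transcript(iid, sid, exon_ids, biotype="protein_coding",
                       gene_id=1, cdna=None, version=1, translation=None):
    return TranscriptView(iid, sid, version, biotype, gene_id,
                          list(exon_ids), cdna=cdna,
                          translation_id=translation,
                          translation_version=1)


class TestTranscriptScoring:
    def _pairing(self, n):
        return {i: 100 + i for i in range(1, n + 1)}

    def test_identical_sets_same_biotype_scores_one(self):
        s = _simple_transcript(1, "T1", [1, 2, 3, 4])
        t = _simple_transcript(2, "TMP", [101, 102, 103, 104])
        sc = score_transcript_pair(s, t, self._pairing(4))
        assert sc.score == 1.0 and sc.eligible

    def test_within_class_biotype_change_costs_ten_percent(self):
        s = _simple_transcript(1, "T1", [1, 2], biotype="snRNA")
        t = _simple_transcript(2, "TMP", [101, 102], biotype="scRNA")
        sc = score_transcript_pair(s, t, self._pairing(2))
        assert sc.score == pytest.approx(0.90)

    def test_coding_to_noncoding_costs_twenty_percent(self):
        s = _simple_transcript(1, "T1", [1, 2], biotype="protein_coding")
        t = _simple_transcript(2, "TMP", [101, 102], biotype="lncRNA")
        sc = score_transcript_pair(s, t, self._pairing(2))
        assert sc.score == pytest.approx(0.80)

    @pytest.mark.parametrize("shared,total,eligible", [
        (1, 4, True),    # exactly 25% is eligible (inclusive boundary)
        (24, 100, False),
        (25, 100, True),
    ])
    def test_intersection_eligibility_boundary(self, shared, total, eligible):
        pairing = {i: 100 + i for i in range(1, shared + 1)}
        s = _simple_transcript(1, "T1", list(range(1, total + 1)))
        t = _simple_transcript(2, "TMP",
                               [100 + i for i in range(1, shared + 1)]
                               + list(range(1000, 1000 + total - shared)))
        sc = score_transcript_pair(s, t, pairing)
        assert sc.eligible == eligible
        assert sc.base == pytest.approx(shared / total)


class TestTranscriptMapping:
    def _sets(self, src_cdna, tgt_cdna, tgt_exon_span=(1, 100)):
        src = _annset([_exon(1, "E1", 1, 100)],
                      [_simple_transcript(1, "T1", [1], cdna=src_cdna,
                                          version=2)],
                      [GeneView(1, "G1", 1, "protein_coding", [1])])
        tgt = _annset([_exon(11, "TMPE", *tgt_exon_span)],
                      [_simple_transcript(11, "TMPT", [11], cdna=tgt_cdna)],
                      [GeneView(11, "TMPG", 1, "protein_coding", [11])])
        return src, tgt

    def test_longer_utr_same_id_new_version(self):
        # exon extended (>=90% shared) and cDNA longer: id kept, version +1
        src, tgt = self._sets("A" * 100, "A" * 105, tgt_exon_span=(1, 105))
        ex = map_exons(src, tgt)
        out = map_transcripts(src, tgt, ex)
        assert out.assignments[11][:2] == ("T1", 3)

    def test_untouched_transcript_keeps_version(self):
        src, tgt = self._sets("A" * 100, "A" * 100)
        ex = map_exons(src, tgt)
        out = map_transcripts(src, tgt, ex)
        assert out.assignments[11][:2] == ("T1", 2)

    def test_all_exons_unmatched_gives_death_and_birth(self):
        src, tgt = self._sets("A" * 100, "C" * 50, tgt_exon_span=(500, 549))
        ex = map_exons(src, tgt)
        out = map_transcripts(src, tgt, ex)
        sid, version, _ = out.assignments[11]
        assert sid != "T1" and version == 1
        assert ("T1", None) in [(e.old_id, e.new_id) for e in out.events]
        assert (None, sid) in [(e.old_id, e.new_id) for e in out.events]


class TestAmbiguityResolution:
    def _tgt_pair(self, biotypes):
        exons = [_exon(11, "A1", 1, 100), _exon(12, "A2", 1, 100,
                                                region="2")]
        ts = [_simple_transcript(11, "TMP1", [11], biotype=biotypes[0],
                                 gene_id=11),
              _simple_transcript(12, "TMP2", [12], biotype=biotypes[1],
                                 gene_id=12)]
        gs = [GeneView(11, "TG1", 1, biotypes[0], [11]),
              GeneView(12, "TG2", 1, biotypes[1], [12])]
        return exons, ts, gs

    def test_matching_biotype_wins_tie(self):
        src = _annset([_exon(1, "E1", 1, 100), _exon(2, "E2", 1, 100,
                                                     region="2")],
                      [_simple_transcript(1, "T1", [1, 2], biotype="snRNA")],
                      [GeneView(1, "G1", 1, "snRNA", [1])])
        exons, ts, gs = self._tgt_pair(("scRNA", "snRNA"))
        tgt = _annset(exons, ts, gs)
        ex = map_exons(src, tgt)
        out = map_transcripts(src, tgt, ex)
        # both targets share one exon (score tie); equal biotype prefers TMP2
        assert out.assignments[12][0] == "T1"

    def test_unresolvable_tie_without_last_resort_discards_ids(self):
        src = _annset([_exon(1, "E1", 1, 100), _exon(2, "E2", 1, 100,
                                                     region="2")],
                      [_simple_transcript(1, "T1", [1, 2], biotype="snRNA")],
                      [GeneView(1, "G1", 1, "snRNA", [1])])
        exons, ts, gs = self._tgt_pair(("snRNA", "snRNA"))
        tgt = _annset(exons, ts, gs)
        ex = map_exons(src, tgt)
        out = map_transcripts(src, tgt, ex, use_last_resort=False)
        assigned = {v[0] for v in out.assignments.values()}
        assert "T1" not in assigned          # old id discarded
        assert len(assigned) == 2            # both targets got fresh ids

    def test_last_resort_picks_lower_internal_id_deterministically(self):
        results = []
        for _ in range(3):
            src = _annset([_exon(1, "E1", 1, 100),
                           _exon(2, "E2", 1, 100, region="2")],
                          [_simple_transcript(1, "T1", [1, 2],
                                              biotype="snRNA")],
                          [GeneView(1, "G1", 1, "snRNA", [1])])
            exons, ts, gs = self._tgt_pair(("snRNA", "snRNA"))
            tgt = _annset(exons, ts, gs)
            out = map_transcripts(src, tgt, map_exons(src, tgt))
            results.append(sorted((k, v[0])
                                  for k, v in out.assignments.items()))
        assert results[0] == results[1] == results[2]
        assert dict(results[0])[11] == "T1"  # lower target internal id wins


class TestGeneMapping:
    def test_gene_with_unchanged_children_keeps_version(self):
        src = _annset([_exon(1, "E1", 1, 100)],
                      [_simple_transcript(1, "T1", [1], cdna="A" * 100,
                                          version=1)],
                      [GeneView(1, "G1", 4, "protein_coding", [1])])
        tgt = _annset([_exon(11, "X", 1, 100)],
                      [_simple_transcript(11, "Y", [11], cdna="A" * 100,
                                          gene_id=11)],
                      [GeneView(11, "Z", 1, "protein_coding", [11])])
        ex = map_exons(src, tgt)
        tr = map_transcripts(src, tgt, ex)
        out = map_genes(src, tgt, tr)
        assert out.assignments[11][:2] == ("G1", 4)

    def test_child_version_bump_increments_gene_version(self):
        src = _annset([_exon(1, "E1", 1, 100)],
                      [_simple_transcript(1, "T1", [1], cdna="A" * 100)],
                      [GeneView(1, "G1", 4, "protein_coding", [1])])
        tgt = _annset([_exon(11, "X", 1, 105)],
                      [_simple_transcript(11, "Y", [11], cdna="A" * 105,
                                          gene_id=11)],
                      [GeneView(11, "Z", 1, "protein_coding", [11])])
        ex = map_exons(src, tgt)
        tr = map_transcripts(src, tgt, ex)
        out = map_genes(src, tgt, tr)
        assert out.assignments[11][:2] == ("G1", 5)


class TestPipeline:
    def test_self_mapping_is_a_fixed_point(self, release_pair):
        """Mapping a release onto an exact copy of itself transfers every id
        with zero version bumps."""
        from genomekit.synthetic import build_release
        store_a, _ = build_release(release_pair.spec)
        store_b, _ = build_release(release_pair.spec)
        before = {}
        for table in ("gene", "transcript", "exon"):
            before[table] = {r[f"{table}_id"]: (r["stable_id"], r["version"])
                             for r in store_b.execute(f"SELECT * FROM {table}")}
        result = run_mapping(store_a, store_b)
        for table, outcome in (("gene", result.genes),
                               ("transcript", result.transcripts),
                               ("exon", result.exons)):
            for iid, (sid, version, _score) in outcome.assignments.items():
                assert (sid, version) == before[table][iid]

    def test_events_are_deterministic_across_runs(self, release_pair):
        from genomekit.synthetic import FixtureSpec, make_release_pair
        runs = []
        for _ in range(2):
            pair = make_release_pair(FixtureSpec(seed=23))
            result = run_mapping(pair.store_a, pair.store_b)
            runs.append([(e.object_type, e.old_id, e.old_version, e.new_id,
                          e.new_version, e.score) for e in result.events])
        assert runs[0] == runs[1]

    def test_version_monotonicity_along_histories(self, release_pair):
        result = run_mapping(release_pair.store_a, release_pair.store_b)
        for ev in result.events:
            if ev.old_id is not None and ev.new_id == ev.old_id:
                assert ev.new_version >= ev.old_version


class TestIdHistory:
    def _three_sessions(self):
        from genomekit.synthetic import FixtureSpec, build_release
        spec = FixtureSpec(seed=31, n_genes=6)
        chain = [build_release(spec)[0] for _ in range(4)]
        for src, tgt in zip(chain, chain[1:]):
            run_mapping(src, tgt)
        return chain[-1]

    def test_unchanged_id_has_event_per_session(self):
        store = self._three_sessions()
        sid = store.execute("SELECT stable_id FROM gene LIMIT 1"
                            ).fetchone()["stable_id"]
        rows = si.id_history(store, sid)
        # one self-event per session for this store (sessions accumulate in
        # the final target only)
        assert all(r[2] == r[4] == sid for r in rows)
        versions = [r[5] for r in rows]
        assert versions == sorted(versions)

    def test_retired_id_chain_ends_with_death(self, release_pair):
        run_mapping(release_pair.store_a, release_pair.store_b)
        deleted = next(e.gene for e in release_pair.plan if e.op == "delete")
        rows = si.id_history(release_pair.store_b, deleted)
        assert rows, "a retired id still has a history"
        assert any(r[2] == deleted and r[4] is None for r in rows)

    def test_unknown_id_gives_empty_chain(self, release_pair):
        assert si.id_history(release_pair.store_b, "NOPE") == []


def test_identifier_allocator_never_collides():
    src = _annset([_exon(1, "GKE00000007", 1, 100)])
    tgt = _annset([_exon(11, "X", 500, 599)])
    alloc = si.IdAllocator(src, tgt)
    assert alloc.new_id("exon") == "GKE00000008"
    assert alloc.new_id("exon") == "GKE00000009"
    assert alloc.new_id("gene") == "GKG00000001"
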