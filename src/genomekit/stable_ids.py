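"""Hierarchical stable-identifier mapping between two annotation releases.

Identity propagates upward from exons: exon pairs sharing >= 90% of their
bases (same assembly, by coordinate overlap) or aligning at >= 90% identity
(across assemblies) keep their stable id.  Transcripts are compared by their
exon sets and stay eligible at >= 25% intersection, with a 10% score penalty
for a biotype change within the same broad functional class and 20% across
classes (e.g. coding to non-coding).  Genes map by shared transcripts, and
translations ride along with their transcripts.

A version increments whenever the underlying object changed: exon
coordinates/sequence, transcript splicing pattern or cDNA, protein sequence,
or any child change for genes.  Sources mapping with comparable scores
(difference < 0.02) to several targets are disambiguated by biotype, then
shared mapped children, then lowest internal id; with the last resort
disabled an unresolved tie discards the old id and mints fresh ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import align
from .genes import broad_class
from .store import Store

#: Minimal shared-base / alignment-identity percentage for an exon pair to
#: keep its stable id.
EXON_THRESHOLD_PERCENT = 90
#: Minimal exon-set intersection percentage for a transcript pair to remain
#: eligible for id transfer.
TRANSCRIPT_MIN_INTERSECTION_PERCENT = 25
#: Score penalties for a biotype change within / across broad classes.
PENALTY_WITHIN_CLASS = 0.10
PENALTY_ACROSS_CLASS = 0.20
#: Two candidate scores closer than this are "comparable" (ambiguous).
AMBIGUITY_MARGIN = 0.02

ID_PREFIX = {"gene": "GKG", "transcript": "GKT", "exon": "GKE",
             "translation": "GKP"}


# -- annotation-set views --------------------------------------------------

@dataclass
class ExonView:
    internal_id: int
    stable_id: str
    version: int
    region_name: str
    start: int
    end: int
    strand: int
    sequence: Optional[str] = None

    def __len__(self):
        return self.end - self.start + 1

    @property
    def coords(self):
        return (self.region_name, self.start, self.end, self.strand)


@dataclass
class TranscriptView:
    internal_id: int
    stable_id: str
    version: int
    biotype: str
    gene_id: int
    exon_ids: list[int]
    cdna: Optional[str] = None
    protein: Optional[str] = None
    translation_id: Optional[str] = None
    translation_version: int = 1


@dataclass
class GeneView:
    internal_id: int
    stable_id: str
    version: int
    biotype: str
    transcript_ids: list[int]


@dataclass
class AnnSet:
    """A flattened, immutable view of one release's gene annotation."""
    exons: dict[int, ExonView] = field(default_factory=dict)
    transcripts: dict[int, TranscriptView] = field(default_factory=dict)
    genes: dict[int, GeneView] = field(default_factory=dict)

    @classmethod
    def from_store(cls, store: Store, with_sequences: bool = True) -> "AnnSet":
        from . import assembly as asm
        from .genes import fetch_genes, spliced_cdna, translate

        out = cls()
        has_dna = store.total_sequence_bytes() > 0 and with_sequences
        for gene in fetch_genes(store):
            t_ids = []
            for t in gene.transcripts:
                e_ids = []
                for e in t.exons:
                    if e.internal_id not in out.exons:
                        seq = (asm.fetch_sequence(store, e.feature.slice())
                               if has_dna else None)
                        out.exons[e.internal_id] = ExonView(
                            internal_id=e.internal_id, stable_id=e.stable_id,
                            version=e.version,
                            region_name=e.feature.region.name,
                            start=e.feature.start, end=e.feature.end,
                            strand=e.feature.strand, sequence=seq)
                    e_ids.append(e.internal_id)
                tv = TranscriptView(
                    internal_id=t.internal_id, stable_id=t.stable_id,
                    version=t.version, biotype=t.biotype,
                    gene_id=gene.internal_id, exon_ids=e_ids,
                    cdna=spliced_cdna(store, t) if has_dna else None,
                    protein=translate(store, t) if has_dna else None,
                    translation_id=(t.translation.stable_id
                                    if t.translation else None),
                    translation_version=(t.translation.version
                                         if t.translation else 1))
                out.transcripts[t.internal_id] = tv
                t_ids.append(t.internal_id)
            out.genes[gene.internal_id] = GeneView(
                internal_id=gene.internal_id, stable_id=gene.stable_id,
                version=gene.version, biotype=gene.biotype,
                transcript_ids=t_ids)
        return out

    def splice_signature(self, t: TranscriptView):
        return tuple(self.exons[eid].coords for eid in t.exon_ids)


class IdAllocator:
    """Mints fresh stable ids that collide with nothing seen so far."""

    def __init__(self, *sets: AnnSet):
        self._next: dict[str, int] = {}
        seen: list[tuple[str, str]] = []
        for s in sets:
            seen += [("gene", g.stable_id) for g in s.genes.values()]
            seen += [("transcript", t.stable_id) for t in s.transcripts.values()]
            seen += [("exon", e.stable_id) for e in s.exons.values()]
            seen += [("translation", t.translation_id)
                     for t in s.transcripts.values() if t.translation_id]
        for obj, prefix in ID_PREFIX.items():
            top = 0
            for kind, sid in seen:
                if kind == obj and sid and sid.startswith(prefix):
                    suffix = sid[len(prefix):]
                    if suffix.isdigit():
                        top = max(top, int(suffix))
            self._next[obj] = top + 1

    def new_id(self, object_type: str) -> str:
        n = self._next[object_type]
        self._next[object_type] = n + 1
        return f"{ID_PREFIX[object_type]}{n:08d}"


@dataclass(frozen=True)
class ExonMatch:
    source_id: int
    target_id: int
    shared_fraction: float
    identity_fraction: Optional[float] = None


@dataclass(frozen=True)
class StableIdEvent:
    object_type: str
    old_id: Optional[str]
    old_version: Optional[int]
    new_id: Optional[str]
    new_version: Optional[int]
    score: Optional[float] = None


@dataclass
class MappingOutcome:
    matches: list = field(default_factory=list)
    #: target internal id -> (stable_id, version, score)
    assignments: dict = field(default_factory=dict)
    #: source internal id -> target internal id for mapped pairs
    pairing: dict = field(default_factory=dict)
    events: list = field(default_factory=list)


# -- exon mapping ----------------------------------------------------------

def shared_base_fraction(a_start: int, a_end: int, b_start: int,
                         b_end: int) -> float:
    """Overlap bases over the longer exon (symmetric, strict denominator)."""
    overlap = min(a_end, b_end) - max(a_start, b_start) + 1
    if overlap <= 0:
        return 0.0
    return overlap / max(a_end - a_start + 1, b_end - b_start + 1)


def _exon_candidates_overlap(src: AnnSet, tgt: AnnSet) -> list[ExonMatch]:
    by_loc: dict[tuple, list[ExonView]] = {}
    for e in tgt.exons.values():
        by_loc.setdefault((e.region_name, e.strand), []).append(e)
    out = []
    for s in src.exons.values():
        for t in by_loc.get((s.region_name, s.strand), ()):
            overlap = min(s.end, t.end) - max(s.start, t.start) + 1
            if overlap <= 0:
                continue
            longest = max(len(s), len(t))
            # integer comparison keeps the 90% boundary exact
            if 100 * overlap >= EXON_THRESHOLD_PERCENT * longest:
                out.append(ExonMatch(s.internal_id, t.internal_id,
                                     overlap / longest))
    return out


def _exon_candidates_alignment(src: AnnSet, tgt: AnnSet) -> list[ExonMatch]:
    out = []
    for s in src.exons.values():
        if not s.sequence:
            continue
        for t in tgt.exons.values():
            if not t.sequence:
                continue
            res = align.global_align(s.sequence, t.sequence)
            if 100 * res.matches >= EXON_THRESHOLD_PERCENT * res.columns:
                out.append(ExonMatch(s.internal_id, t.internal_id,
                                     res.identity, res.identity))
    return out


def map_exons(src: AnnSet, tgt: AnnSet, same_assembly: bool = True,
              allocator: Optional[IdAllocator] = None) -> MappingOutcome:
    """Match exons and assign target stable ids/versions.

    Same assembly: candidate pairs overlap on the same region and strand and
    are retained at >= 90% shared bases (overlap over the longer exon).
    Across assemblies: retained at >= 90% global-alignment identity.  Each
    exon joins at most one accepted match, greedily by descending fraction
    (ties to the lower internal id).  The id keeps its version only on a
    perfect coordinate-and-sequence match.
    """
    allocator = allocator or IdAllocator(src, tgt)
    candidates = (_exon_candidates_overlap(src, tgt) if same_assembly
                  else _exon_candidates_alignment(src, tgt))
    candidates.sort(key=lambda m: (-m.shared_fraction, m.source_id, m.target_id))
    outcome = MappingOutcome()
    used_src: set[int] = set()
    used_tgt: set[int] = set()
    for m in candidates:
        if m.source_id in used_src or m.target_id in used_tgt:
            continue
        used_src.add(m.source_id)
        used_tgt.add(m.target_id)
        outcome.matches.append(m)
        s, t = src.exons[m.source_id], tgt.exons[m.target_id]
        same_coords = s.coords == t.coords
        same_seq = (s.sequence == t.sequence
                    if (s.sequence is not None and t.sequence is not None)
                    else same_assembly and same_coords)
        perfect = (same_coords and same_seq) if same_assembly else \
            (same_seq and len(s) == len(t))
        version = s.version if perfect else s.version + 1
        outcome.assignments[m.target_id] = (s.stable_id, version,
                                            m.shared_fraction)
        outcome.pairing[m.source_id] = m.target_id
        outcome.events.append(StableIdEvent(
            "exon", s.stable_id, s.version, s.stable_id, version,
            m.shared_fraction))
    for t in sorted(tgt.exons.values(), key=lambda e: e.internal_id):
        if t.internal_id not in used_tgt:
            new = allocator.new_id("exon")
            outcome.assignments[t.internal_id] = (new, 1, None)
            outcome.events.append(StableIdEvent("exon", None, None, new, 1))
    for s in sorted(src.exons.values(), key=lambda e: e.internal_id):
        if s.internal_id not in used_src:
            outcome.events.append(StableIdEvent(
                "exon", s.stable_id, s.version, None, None))
    return outcome


# -- transcript scoring ----------------------------------------------------

def biotype_penalty(src_biotype: str, tgt_biotype: str) -> float:
    """0 for equal biotypes, 0.10 within one broad class, 0.20 across."""
    if src_biotype == tgt_biotype:
        return 0.0
    if broad_class(src_biotype) == broad_class(tgt_biotype):
        return PENALTY_WITHIN_CLASS
    return PENALTY_ACROSS_CLASS


@dataclass(frozen=True)
class TranscriptScore:
    shared_exons: int
    base: float
    penalty: float
    score: float
    eligible: bool


def score_transcript_pair(src_t: TranscriptView, tgt_t: TranscriptView,
                          exon_pairing: dict[int, int]) -> TranscriptScore:
    """Exon-set intersection score with the biotype penalty applied.

    base = matched exon pairs / max(source exon count, target exon count);
    the pair stays eligible at 25% or greater intersection; the penalty
    multiplies the base score.
    """
    tgt_exons = set(tgt_t.exon_ids)
    shared = sum(1 for eid in src_t.exon_ids
                 if exon_pairing.get(eid) in tgt_exons)
    denom = max(len(src_t.exon_ids), len(tgt_t.exon_ids))
    base = shared / denom if denom else 0.0
    eligible = 100 * shared >= TRANSCRIPT_MIN_INTERSECTION_PERCENT * denom
    penalty = biotype_penalty(src_t.biotype, tgt_t.biotype)
    return TranscriptScore(shared, base, penalty, base * (1.0 - penalty),
                           eligible and shared > 0)


# -- ambiguity resolution --------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    target_id: int
    score: float
    same_biotype: bool
    shared_children: int


def resolve_ambiguities(candidates: list[Candidate],
                        use_last_resort: bool = True) -> Optional[int]:
    """Pick one target from comparably-scored candidates, or None to discard.

    Cascade: (1) prefer an equal biotype; (2) prefer more shared mapped
    parent/child ids; (3) as a deterministic last resort, the lower target
    internal id.  When the last resort is disabled and steps 1-2 leave a
    tie, all old ids are discarded (None).
    """
    pool = list(candidates)
    preferred = [c for c in pool if c.same_biotype]
    if preferred and len(preferred) < len(pool):
        pool = preferred
    if len(pool) > 1:
        best_children = max(c.shared_children for c in pool)
        narrowed = [c for c in pool if c.shared_children == best_children]
        if len(narrowed) < len(pool):
            pool = narrowed
    if len(pool) == 1:
        return pool[0].target_id
    if use_last_resort:
        return min(pool, key=lambda c: c.target_id).target_id
    return None


def _greedy_assign(pair_scores: dict[tuple[int, int], tuple[float, bool, int]],
                   use_last_resort: bool) -> tuple[dict[int, int], set[int]]:
    """Source-major greedy matching with the ambiguity cascade.

    ``pair_scores`` maps (source id, target id) to (score, same_biotype,
    shared_children).  Sources are served in order of their best score;
    returns the chosen pairing and the set of sources discarded as
    unresolvable."""
    by_source: dict[int, list[tuple[int, float, bool, int]]] = {}
    for (s, t), (score, same_bt, shared) in pair_scores.items():
        by_source.setdefault(s, []).append((t, score, same_bt, shared))
    order = sorted(by_source,
                   key=lambda s: (-max(c[1] for c in by_source[s]), s))
    used_tgt: set[int] = set()
    pairing: dict[int, int] = {}
    discarded: set[int] = set()
    for s in order:
        open_cands = [c for c in by_source[s] if c[0] not in used_tgt]
        if not open_cands:
            continue
        best = max(c[1] for c in open_cands)
        comparable = [Candidate(t, sc, bt, sh) for (t, sc, bt, sh) in open_cands
                      if best - sc < AMBIGUITY_MARGIN]
        if len(comparable) == 1:
            chosen = comparable[0].target_id
        else:
            chosen = resolve_ambiguities(comparable, use_last_resort)
        if chosen is None:
            discarded.add(s)
            continue
        pairing[s] = chosen
        used_tgt.add(chosen)
    return pairing, discarded


# -- transcript / gene / translation mapping -------------------------------

def map_transcripts(src: AnnSet, tgt: AnnSet, exon_outcome: MappingOutcome,
                    allocator: Optional[IdAllocator] = None,
                    same_assembly: bool = True,
                    use_last_resort: bool = True) -> MappingOutcome:
    allocator = allocator or IdAllocator(src, tgt)
    exon_pairing = exon_outcome.pairing
    # transcript pairs joined by at least one matched exon
    tgt_by_exon: dict[int, list[int]] = {}
    for t in tgt.transcripts.values():
        for eid in t.exon_ids:
            tgt_by_exon.setdefault(eid, []).append(t.internal_id)
    pair_scores: dict[tuple[int, int], tuple[float, bool, int]] = {}
    for s_t in src.transcripts.values():
        seen_targets: set[int] = set()
        for eid in s_t.exon_ids:
            mapped = exon_pairing.get(eid)
            if mapped is None:
                continue
            for t_id in tgt_by_exon.get(mapped, ()):
                seen_targets.add(t_id)
        for t_id in seen_targets:
            t_t = tgt.transcripts[t_id]
            sc = score_transcript_pair(s_t, t_t, exon_pairing)
            if sc.eligible:
                pair_scores[(s_t.internal_id, t_id)] = (
                    sc.score, s_t.biotype == t_t.biotype, sc.shared_exons)
    pairing, discarded = _greedy_assign(pair_scores, use_last_resort)
    outcome = MappingOutcome(pairing=pairing)
    for s_id, t_id in sorted(pairing.items()):
        s_t, t_t = src.transcripts[s_id], tgt.transcripts[t_id]
        same_splicing = (src.splice_signature(s_t) == tgt.splice_signature(t_t)
                         if same_assembly else False)
        if s_t.cdna is not None and t_t.cdna is not None:
            same_cdna = s_t.cdna == t_t.cdna
            perfect = same_cdna and (same_splicing if same_assembly else True)
        else:
            perfect = same_splicing
        version = s_t.version if perfect else s_t.version + 1
        score = pair_scores[(s_id, t_id)][0]
        outcome.assignments[t_id] = (s_t.stable_id, version, score)
        outcome.events.append(StableIdEvent(
            "transcript", s_t.stable_id, s_t.version, s_t.stable_id, version,
            score))
    mapped_tgt = set(pairing.values())
    for t_t in sorted(tgt.transcripts.values(), key=lambda t: t.internal_id):
        if t_t.internal_id not in mapped_tgt:
            new = allocator.new_id("transcript")
            outcome.assignments[t_t.internal_id] = (new, 1, None)
            outcome.events.append(StableIdEvent(
                "transcript", None, None, new, 1))
    for s_t in sorted(src.transcripts.values(), key=lambda t: t.internal_id):
        if s_t.internal_id not in pairing:
            outcome.events.append(StableIdEvent(
                "transcript", s_t.stable_id, s_t.version, None, None,
                None if s_t.internal_id not in discarded else 0.0))
    return outcome


def map_genes(src: AnnSet, tgt: AnnSet, transcript_outcome: MappingOutcome,
              allocator: Optional[IdAllocator] = None,
              use_last_resort: bool = True) -> MappingOutcome:
    """Gene ids follow shared transcripts; any child id or version change
    increments the gene version."""
    allocator = allocator or IdAllocator(src, tgt)
    t_pairing = transcript_outcome.pairing
    pair_scores: dict[tuple[int, int], tuple[float, bool, int]] = {}
    shared_count: dict[tuple[int, int], int] = {}
    for s_tid, t_tid in t_pairing.items():
        g_s = src.transcripts[s_tid].gene_id
        g_t = tgt.transcripts[t_tid].gene_id
        shared_count[(g_s, g_t)] = shared_count.get((g_s, g_t), 0) + 1
    for (g_s, g_t), shared in shared_count.items():
        sg, tg = src.genes[g_s], tgt.genes[g_t]
        denom = max(len(sg.transcript_ids), len(tg.transcript_ids))
        score = shared / denom if denom else 0.0
        pair_scores[(g_s, g_t)] = (score, sg.biotype == tg.biotype, shared)
    pairing, discarded = _greedy_assign(pair_scores, use_last_resort)
    outcome = MappingOutcome(pairing=pairing)
    for g_s, g_t in sorted(pairing.items()):
        sg, tg = src.genes[g_s], tgt.genes[g_t]
        src_children = sorted(
            (src.transcripts[t].stable_id, src.transcripts[t].version)
            for t in sg.transcript_ids)
        tgt_children = sorted(
            transcript_outcome.assignments[t][:2] for t in tg.transcript_ids)
        version = sg.version if src_children == tgt_children else sg.version + 1
        score = pair_scores[(g_s, g_t)][0]
        outcome.assignments[g_t] = (sg.stable_id, version, score)
        outcome.events.append(StableIdEvent(
            "gene", sg.stable_id, sg.version, sg.stable_id, version, score))
    mapped_tgt = set(pairing.values())
    for tg in sorted(tgt.genes.values(), key=lambda g: g.internal_id):
        if tg.internal_id not in mapped_tgt:
            new = allocator.new_id("gene")
            outcome.assignments[tg.internal_id] = (new, 1, None)
            outcome.events.append(StableIdEvent("gene", None, None, new, 1))
    for sg in sorted(src.genes.values(), key=lambda g: g.internal_id):
        if sg.internal_id not in pairing:
            outcome.events.append(StableIdEvent(
                "gene", sg.stable_id, sg.version, None, None,
                0.0 if sg.internal_id in discarded else None))
    return outcome


def map_translations(src: AnnSet, tgt: AnnSet,
                     transcript_outcome: MappingOutcome,
                     allocator: Optional[IdAllocator] = None) -> MappingOutcome:
    """Protein ids ride on the transcript mapping; the version increments
    when the protein sequence changed."""
    allocator = allocator or IdAllocator(src, tgt)
    outcome = MappingOutcome()
    mapped_tgt: set[int] = set()
    for s_tid, t_tid in sorted(transcript_outcome.pairing.items()):
        s_t, t_t = src.transcripts[s_tid], tgt.transcripts[t_tid]
        if s_t.translation_id and t_t.translation_id is not None:
            same_protein = (s_t.protein == t_t.protein
                            if (s_t.protein is not None
                                and t_t.protein is not None) else True)
            version = (s_t.translation_version if same_protein
                       else s_t.translation_version + 1)
            outcome.assignments[t_tid] = (s_t.translation_id, version, None)
            outcome.pairing[s_tid] = t_tid
            outcome.events.append(StableIdEvent(
                "translation", s_t.translation_id, s_t.translation_version,
                s_t.translation_id, version))
            mapped_tgt.add(t_tid)
    for t_t in sorted(tgt.transcripts.values(), key=lambda t: t.internal_id):
        if t_t.translation_id is not None and t_t.internal_id not in mapped_tgt:
            new = allocator.new_id("translation")
            outcome.assignments[t_t.internal_id] = (new, 1, None)
            outcome.events.append(StableIdEvent(
                "translation", None, None, new, 1))
    for s_t in sorted(src.transcripts.values(), key=lambda t: t.internal_id):
        if s_t.translation_id and s_t.internal_id not in outcome.pairing:
            outcome.events.append(StableIdEvent(
                "translation", s_t.translation_id, s_t.translation_version,
                None, None))
    return outcome


# -- full pipeline ---------------------------------------------------------

@dataclass
class MappingResult:
    session_id: Optional[int]
    exons: MappingOutcome
    transcripts: MappingOutcome
    genes: MappingOutcome
    translations: MappingOutcome

    @property
    def events(self) -> list[StableIdEvent]:
        return (self.genes.events + self.transcripts.events
                + self.translations.events + self.exons.events)


def run_mapping(source_store: Store, target_store: Store,
                same_assembly: bool = True, source_label: str = "source",
                target_label: str = "target", seed: int = 0,
                apply: bool = True,
                use_last_resort: bool = True) -> MappingResult:
    """Run the full exon -> transcript -> translation -> gene pipeline.

    When ``apply`` is true the target store's stable ids and versions are
    rewritten in place and the events recorded under a new mapping session.
    """
    src = AnnSet.from_store(source_store)
    tgt = AnnSet.from_store(target_store)
    allocator = IdAllocator(src, tgt)
    exons = map_exons(src, tgt, same_assembly, allocator)
    transcripts = map_transcripts(src, tgt, exons, allocator, same_assembly,
                                  use_last_resort)
    translations = map_translations(src, tgt, transcripts, allocator)
    genes = map_genes(src, tgt, transcripts, allocator, use_last_resort)
    session_id = None
    if apply:
        cur = target_store.execute(
            "INSERT INTO mapping_session(source, target, same_assembly, "
            "created, seed) VALUES (?,?,?,datetime('now'),?)",
            (source_label, target_label, int(same_assembly), seed))
        session_id = cur.lastrowid
        for table, outcome, id_col in (
                ("exon", exons, "exon_id"),
                ("transcript", transcripts, "transcript_id"),
                ("gene", genes, "gene_id")):
            for internal_id, (sid, version, _score) in outcome.assignments.items():
                target_store.execute(
                    f"UPDATE {table} SET stable_id=?, version=? WHERE {id_col}=?",
                    (sid, version, internal_id))
        for t_internal, (sid, version, _s) in translations.assignments.items():
            target_store.execute(
                "UPDATE translation SET stable_id=?, version=? "
                "WHERE transcript_id=?", (sid, version, t_internal))
        result = MappingResult(session_id, exons, transcripts, genes,
                               translations)
        for ev in result.events:
            target_store.execute(
                "INSERT INTO stable_id_event VALUES (?,?,?,?,?,?,?)",
                (session_id, ev.object_type, ev.old_id, ev.old_version,
                 ev.new_id, ev.new_version, ev.score))
        target_store.commit()
        return result
    return MappingResult(None, exons, transcripts, genes, translations)


def id_history(store: Store, stable_id: str) -> list[tuple]:
    """The event chain for a stable id across all recorded sessions.

    Follows renames in both directions (merges and splits included); an
    unknown id yields an empty chain.  Rows are (session_id, object_type,
    old_id, old_version, new_id, new_version, score) ordered by session.
    """
    frontier = {stable_id}
    known: set[str] = set()
    rows: list[tuple] = []
    seen_rows: set[tuple] = set()
    while frontier:
        current = frontier.pop()
        if current in known:
            continue
        known.add(current)
        for r in store.execute(
                "SELECT * FROM stable_id_event WHERE old_stable_id=? "
                "OR new_stable_id=?", (current, current)).fetchall():
            tup = (r["mapping_session_id"], r["object_type"],
                   r["old_stable_id"], r["old_version"], r["new_stable_id"],
                   r["new_version"], r["score"])
            if tup in seen_rows:
                continue
            seen_rows.add(tup)
            rows.append(tup)
            for linked in (r["old_stable_id"], r["new_stable_id"]):
                if linked and linked not in known:
                    frontier.add(linked)
    rows.sort(key=lambda r: (r[0], r[1], r[2] or "", r[4] or ""))
    return rows
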