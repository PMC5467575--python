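"""External-reference linking and gene naming.

Four linkage methods connect internal genes/transcripts/proteins to external
accessions: direct (third-party supplied), location overlap (shared genomic
exon space), checksum (MD5 of the sequence) and sequence alignment.  Method
priority for choosing a gene's display name is direct > location > checksum
> alignment; within a method, configured source ranks decide (a nomenclature
committee outranks everything else), and a gene with no eligible link falls
back to a clone-derived name.  Winning sources may pull in transitive child
links, recorded with info type DEPENDENT.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import align
from .model import ModelError
from .store import Store

log = logging.getLogger(__name__)

METHODS = ("direct", "location_overlap", "checksum", "alignment")
METHOD_PRIORITY = {"direct": 0, "location_overlap": 1, "checksum": 2,
                   "alignment": 3}
INFO_TYPE_BY_METHOD = {"direct": "DIRECT", "location_overlap":
                       "COORDINATE_OVERLAP", "checksum": "CHECKSUM",
                       "alignment": "SEQUENCE_MATCH"}


@dataclass(frozen=True)
class XrefSource:
    name: str
    method: str
    priority: int  # unique rank; lower = more trusted for naming
    naming_eligible: bool = False
    transitive_children: tuple = ()

    def __post_init__(self):
        if self.method not in METHODS:
            raise ModelError(f"unknown xref method {self.method!r}")


@dataclass(frozen=True)
class Xref:
    source: str
    accession: str
    display_label: str
    object_type: str          # gene | transcript | translation
    object_id: str            # stable id of the linked object
    info_type: str
    query_identity: Optional[float] = None
    target_identity: Optional[float] = None
    cigar: Optional[str] = None
    evidence_code: Optional[str] = None

    def __post_init__(self):
        if self.info_type == "SEQUENCE_MATCH" and (
                self.query_identity is None or self.cigar is None):
            raise ModelError(
                "alignment-based xrefs must carry identities and a CIGAR")


def _md5(seq: str) -> str:
    return hashlib.md5(seq.upper().encode()).hexdigest()


def match_direct(source: XrefSource,
                 links: Iterable[tuple[str, str, str]],
                 object_type: str = "gene") -> list[Xref]:
    """Third-party supplied accession -> stable-id links."""
    return [Xref(source.name, acc, label or acc, object_type, sid, "DIRECT")
            for acc, sid, label in links]


def match_checksum(source: XrefSource, external: dict[str, str],
                   internal: dict[str, str],
                   object_type: str = "translation") -> list[Xref]:
    """Link on equal MD5 of the uppercased sequences (order-symmetric)."""
    by_md5: dict[str, list[str]] = {}
    for sid, seq in internal.items():
        by_md5.setdefault(_md5(seq), []).append(sid)
    out = []
    for acc in sorted(external):
        for sid in sorted(by_md5.get(_md5(external[acc]), ())):
            out.append(Xref(source.name, acc, acc, object_type, sid,
                            "CHECKSUM"))
    return out


def match_alignment(source: XrefSource, external: dict[str, str],
                    internal: dict[str, str], min_identity: float = 90.0,
                    best_n: int = 1, mode: str = "local",
                    object_type: str = "translation") -> list[Xref]:
    """Align every external sequence against the internal set.

    Per external accession the hits are filtered to identity >= the minimum
    threshold and limited to the ``best_n`` distinct identity levels; hits
    tied at a kept level are all linked.  Query/target identities (matches
    over query/target length, as percentages) and a CIGAR string are
    recorded on every link.
    """
    if not 0 < min_identity <= 100:
        raise ModelError("min_identity must be in (0, 100]")
    if best_n < 1:
        raise ModelError("best_n must be >= 1")
    aligner = align.local_align if mode == "local" else align.global_align
    out = []
    for acc in sorted(external):
        qseq = external[acc]
        if not qseq:
            log.warning("skipping empty external sequence %s", acc)
            continue
        hits = []
        for sid in sorted(internal):
            tseq = internal[sid]
            if not tseq:
                log.warning("skipping empty internal sequence %s", sid)
                continue
            res = aligner(qseq, tseq)
            q_ident = align.identity_percent(res.matches, len(qseq))
            t_ident = align.identity_percent(res.matches, len(tseq))
            if q_ident >= min_identity:
                hits.append((q_ident, sid, t_ident, res.cigar))
        levels = sorted({round(h[0], 6) for h in hits}, reverse=True)[:best_n]
        for q_ident, sid, t_ident, cigar in sorted(hits,
                                                   key=lambda h: (-h[0], h[1])):
            if round(q_ident, 6) in levels:
                out.append(Xref(source.name, acc, acc, object_type, sid,
                                "SEQUENCE_MATCH", query_identity=q_ident,
                                target_identity=t_ident, cigar=cigar))
    return out


ExonSpan = tuple[str, int, int, int]  # (region name, start, end, strand)


def _overlap_bases(a: Iterable[ExonSpan], b: Iterable[ExonSpan]) -> int:
    total = 0
    for (ra, sa, ea, stra) in a:
        for (rb, sb, eb, strb) in b:
            if ra == rb and stra == strb:
                total += max(0, min(ea, eb) - max(sa, sb) + 1)
    return total


def match_overlap(source: XrefSource,
                  external: dict[str, list[ExonSpan]],
                  internal: dict[str, list[ExonSpan]],
                  object_type: str = "transcript") -> list[Xref]:
    """Link each external record to the internal transcript with maximal
    genomic exon-overlap bases (> 0); ties break to the lower stable id."""
    out = []
    for acc in sorted(external):
        best: Optional[tuple[int, str]] = None
        for sid in sorted(internal):
            ov = _overlap_bases(external[acc], internal[sid])
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, sid)
        if best is not None:
            out.append(Xref(source.name, acc, acc, object_type, best[1],
                            "COORDINATE_OVERLAP"))
    return out


# -- priority resolution and naming ----------------------------------------

@dataclass
class NamingResult:
    #: gene stable id -> (display name, winning source name or "clone")
    names: dict[str, tuple[str, str]] = field(default_factory=dict)
    dependent_xrefs: list[Xref] = field(default_factory=list)


def resolve_and_name(
        xrefs: Iterable[Xref],
        sources: dict[str, XrefSource],
        object_to_gene: dict[str, str],
        clone_names: dict[str, str],
        transitive_links: Optional[dict] = None) -> NamingResult:
    """Choose exactly one display name per gene, deterministically.

    All xrefs attached to a gene or its children compete: method priority
    first (direct > location overlap > checksum > alignment), then the
    configured source rank, then accession.  Only naming-eligible sources
    can name a gene; a gene whose xrefs are all ineligible — or that has
    none — takes its clone name.  The per-gene winning xref additionally
    imports its source's transitive child links as DEPENDENT xrefs.

    ``transitive_links`` maps (source name, accession) to an iterable of
    (child source, child accession, child label).
    """
    per_gene: dict[str, list[Xref]] = {}
    for x in xrefs:
        gene = object_to_gene.get(x.object_id, x.object_id)
        per_gene.setdefault(gene, []).append(x)
    result = NamingResult()
    transitive_links = transitive_links or {}
    for gene in sorted(set(object_to_gene.values()) | set(per_gene)):
        candidates = per_gene.get(gene, [])

        def rank(x: Xref):
            src = sources[x.source]
            return (METHOD_PRIORITY[src.method], src.priority, x.accession)

        candidates = sorted(candidates, key=rank)
        if candidates:
            winner = candidates[0]
            src = sources[winner.source]
            for child in transitive_links.get(
                    (winner.source, winner.accession), ()):
                child_source, child_acc, child_label = child
                if child_source in src.transitive_children:
                    result.dependent_xrefs.append(Xref(
                        child_source, child_acc, child_label,
                        winner.object_type, winner.object_id, "DEPENDENT"))
        namers = [x for x in candidates if sources[x.source].naming_eligible]
        if namers:
            result.names[gene] = (namers[0].display_label, namers[0].source)
        else:
            result.names[gene] = (
                clone_names.get(gene, f"{gene}-CLONE"), "clone")
    return result


# -- persistence -----------------------------------------------------------

def store_xrefs(store: Store, xrefs: Iterable[Xref]) -> int:
    n = 0
    for x in xrefs:
        cur = store.execute(
            "INSERT INTO xref(source, accession, display_label, info_type, "
            "query_identity, target_identity, cigar, evidence_code) "
            "VALUES (?,?,?,?,?,?,?,?)",
            (x.source, x.accession, x.display_label, x.info_type,
             x.query_identity, x.target_identity, x.cigar, x.evidence_code))
        store.execute(
            "INSERT INTO object_xref(xref_id, object_type, object_stable_id) "
            "VALUES (?,?,?)", (cur.lastrowid, x.object_type, x.object_id))
        n += 1
    store.commit()
    return n
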