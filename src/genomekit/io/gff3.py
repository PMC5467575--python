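"""GFF3 import/export of gene models, operons and simple features.

GFF3 is the canonical annotation interchange format here; coordinates are
1-based inclusive, matching the internal convention.  Stable-id versions
are encoded as ``stable_id.version`` inside ID attributes.  Parsing goes
through gffutils.
"""

from __future__ import annotations

from typing import Iterable, Optional

import gffutils

from ..genes import Exon, Gene, Operon, OperonTranscript, Transcript, Translation
from ..model import Feature, ModelError
from ..store import Store

SOURCE = "genomekit"


def _versioned(stable_id: str, version: int) -> str:
    return f"{stable_id}.{version}"


def _split_versioned(text: str) -> tuple[str, int]:
    if "." in text and text.rsplit(".", 1)[1].isdigit():
        sid, v = text.rsplit(".", 1)
        return sid, int(v)
    return text, 1


def _strand_txt(strand: int) -> str:
    return "+" if strand == 1 else "-"


def _attr(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def _cds_genomic_ranges(t: Transcript) -> list[tuple[int, int]]:
    """Genomic (start, end) of the coding part of each coding exon."""
    tr = t.translation
    if tr is None:
        return []
    strand = t.feature.strand
    ranges = []
    in_cds = False
    for e in t.exons:
        lo, hi = e.feature.start, e.feature.end
        first = e.stable_id == tr.start_exon.stable_id
        last = e.stable_id == tr.end_exon.stable_id
        if first:
            in_cds = True
            if strand == 1:
                lo = e.feature.start + tr.seq_start - 1
            else:
                hi = e.feature.end - tr.seq_start + 1
        if not in_cds:
            continue
        if last:
            if strand == 1:
                hi = e.feature.start + tr.seq_end - 1
            else:
                lo = e.feature.end - tr.seq_end + 1
        if lo <= hi:
            ranges.append((lo, hi))
        if last:
            break
    return ranges


def write_gff3(path, genes: Iterable[Gene] = (),
               operons: Iterable[Operon] = (),
               features: Iterable[Feature] = ()) -> int:
    """Serialise annotation to GFF3; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            gf = gene.feature
            gid = f"gene:{_versioned(gene.stable_id, gene.version)}"
            fh.write("\t".join(map(str, (
                gf.region.name, SOURCE, "gene", gf.start, gf.end, ".",
                _strand_txt(gf.strand), ".",
                _attr([("ID", gid), ("biotype", gene.biotype)])))) + "\n")
            n += 1
            for t in gene.transcripts:
                tf = t.feature
                tid = f"transcript:{_versioned(t.stable_id, t.version)}"
                fh.write("\t".join(map(str, (
                    tf.region.name, SOURCE, "mRNA", tf.start, tf.end, ".",
                    _strand_txt(tf.strand), ".",
                    _attr([("ID", tid), ("Parent", gid),
                           ("biotype", t.biotype)])))) + "\n")
                n += 1
                for e in t.exons:
                    ef = e.feature
                    # the line ID is made unique per transcript; the stable
                    # identity travels in the exon_id attribute
                    fh.write("\t".join(map(str, (
                        ef.region.name, SOURCE, "exon", ef.start, ef.end,
                        ".", _strand_txt(ef.strand), ".",
                        _attr([("ID", f"exon:{e.stable_id}-{t.stable_id}"),
                               ("Parent", tid),
                               ("exon_id", _versioned(e.stable_id, e.version)),
                               ("phase_attr", str(e.phase))])))) + "\n")
                    n += 1
                if t.translation is not None:
                    pv = _versioned(t.translation.stable_id,
                                    t.translation.version)
                    for part, (lo, hi) in enumerate(_cds_genomic_ranges(t)):
                        fh.write("\t".join(map(str, (
                            tf.region.name, SOURCE, "CDS", lo, hi, ".",
                            _strand_txt(tf.strand), "0",
                            _attr([("ID", f"cds:{t.stable_id}-{part}"),
                                   ("Parent", tid),
                                   ("protein_id", pv)])))) + "\n")
                        n += 1
        for op in operons:
            of = op.feature
            oid = f"operon:{op.display_label}"
            fh.write("\t".join(map(str, (
                of.region.name, SOURCE, "operon", of.start, of.end, ".",
                _strand_txt(of.strand), ".",
                _attr([("ID", oid), ("Name", op.display_label)])))) + "\n")
            n += 1
            for ot in op.transcripts:
                otf = ot.feature
                fh.write("\t".join(map(str, (
                    otf.region.name, SOURCE, "mRNA", otf.start, otf.end, ".",
                    _strand_txt(otf.strand), ".",
                    _attr([("ID", f"operon_transcript:{ot.display_label}"),
                           ("Parent", oid),
                           ("genes", ",".join(ot.gene_stable_ids))])))) + "\n")
                n += 1
        for f in features:
            ident = []
            if f.stable_id:
                ident.append(("ID", _versioned(f.stable_id, f.version or 1)))
            ident.append(("analysis", f.analysis))
            fh.write("\t".join(map(str, (
                f.region.name, SOURCE, f.feature_type, f.start, f.end, ".",
                _strand_txt(f.strand), ".", _attr(ident) or "."))) + "\n")
            n += 1
    return n


def _region_for(store: Store, name: str, species_id: int):
    for cs in store.coord_systems(species_id=species_id):
        try:
            return store.region(name, cs)
        except Exception:
            continue
    raise ModelError(f"GFF3 references unknown region {name!r}")


def read_gff3_genes(store: Store, path, species_id: int = 1,
                    analysis: str = "import") -> list[Gene]:
    """Parse gene/mRNA/exon/CDS records into gene graphs (not yet stored)."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes: list[Gene] = []
    for grec in db.features_of_type("gene"):
        region = _region_for(store, grec.seqid, species_id)
        strand = -1 if grec.strand == "-" else 1
        g_sid, g_ver = _split_versioned(grec.id.split(":", 1)[-1])
        gene = Gene(
            feature=Feature("gene", region, grec.start, grec.end, strand,
                            analysis=analysis, stable_id=g_sid, version=g_ver),
            stable_id=g_sid, version=g_ver,
            biotype=grec.attributes.get("biotype", ["protein_coding"])[0],
            transcripts=[])
        for trec in db.children(grec, featuretype="mRNA", order_by="start"):
            t_sid, t_ver = _split_versioned(trec.id.split(":", 1)[-1])
            exons = []
            for erec in db.children(trec, featuretype="exon", order_by="start"):
                e_sid, e_ver = _split_versioned(
                    erec.attributes["exon_id"][0])
                phase = int(erec.attributes.get("phase_attr", ["-1"])[0])
                exons.append(Exon(
                    feature=Feature("exon", region, erec.start, erec.end,
                                    strand, analysis=analysis,
                                    stable_id=e_sid, version=e_ver),
                    stable_id=e_sid, version=e_ver, phase=phase))
            if strand == -1:
                exons.sort(key=lambda e: e.feature.start, reverse=True)
            translation = _translation_from_cds(db, trec, exons, strand)
            gene.transcripts.append(Transcript(
                feature=Feature("transcript", region, trec.start, trec.end,
                                strand, analysis=analysis, stable_id=t_sid,
                                version=t_ver),
                stable_id=t_sid, version=t_ver,
                biotype=trec.attributes.get("biotype", ["protein_coding"])[0],
                exons=exons, translation=translation))
        genes.append(gene)
    return genes


def _translation_from_cds(db, trec, exons: list[Exon],
                          strand: int) -> Optional[Translation]:
    cds = list(db.children(trec, featuretype="CDS", order_by="start"))
    if not cds:
        return None
    p_sid, p_ver = _split_versioned(cds[0].attributes["protein_id"][0])
    lo = min(c.start for c in cds)
    hi = max(c.end for c in cds)
    cds_5p, cds_3p = (lo, hi) if strand == 1 else (hi, lo)
    start_exon = end_exon = None
    seq_start = seq_end = None
    for e in exons:
        if e.feature.start <= cds_5p <= e.feature.end and start_exon is None:
            start_exon = e
            seq_start = (cds_5p - e.feature.start + 1 if strand == 1
                         else e.feature.end - cds_5p + 1)
        if e.feature.start <= cds_3p <= e.feature.end:
            end_exon = e
            seq_end = (cds_3p - e.feature.start + 1 if strand == 1
                       else e.feature.end - cds_3p + 1)
    if start_exon is None or end_exon is None:
        raise ModelError(f"CDS of {trec.id} lies outside its exons")
    return Translation(stable_id=p_sid, version=p_ver, start_exon=start_exon,
                       seq_start=seq_start, end_exon=end_exon, seq_end=seq_end)


def export_query_gff3(path, features: Iterable[Feature]) -> int:
    """Write range-query results as plain GFF3 feature lines."""
    return write_gff3(path, features=features)
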