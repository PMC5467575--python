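"""Pairwise alignment utilities: identity fractions and CIGAR strings.

Global mode (Needleman-Wunsch, match +1 / mismatch -1 / gap -2) is used for
exon-to-exon comparison in cross-assembly stable-ID mapping; local mode
(Smith-Waterman, same scores) for linking external sequences of unequal
extent (e.g. an mRNA with extra UTR against a transcript).  Identity is
counted as matching columns over aligned columns (global) or over the two
sequence lengths (the xref convention).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -2.0, -2.0


@dataclass(frozen=True)
class AlignmentResult:
    matches: int          # identical aligned columns
    columns: int          # aligned columns including gaps
    cigar: str            # M/I/D runs, I = insertion in the query
    query_span: int       # aligned length on the query
    target_span: int      # aligned length on the target
    score: float

    @property
    def identity(self) -> float:
        """matches / alignment columns, in [0, 1]."""
        return self.matches / self.columns if self.columns else 0.0


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _summarise(alignment, query: str, target: str) -> AlignmentResult:
    matches = columns = 0
    cigar_ops: list[tuple[str, int]] = []

    def push(op: str, n: int):
        if n == 0:
            return
        if cigar_ops and cigar_ops[-1][0] == op:
            cigar_ops[-1] = (op, cigar_ops[-1][1] + n)
        else:
            cigar_ops.append((op, n))

    blocks = alignment.aligned  # pairs of (query block, target block)
    q_blocks, t_blocks = blocks[0], blocks[1]
    prev_q_end = prev_t_end = None
    q_span = t_span = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if prev_q_end is not None:
            push("I", qs - prev_q_end)
            push("D", ts - prev_t_end)
            columns += (qs - prev_q_end) + (ts - prev_t_end)
        push("M", qe - qs)
        for i in range(qe - qs):
            if query[qs + i].upper() == target[ts + i].upper():
                matches += 1
        columns += qe - qs
        q_span += qe - qs
        t_span += te - ts
        prev_q_end, prev_t_end = qe, te
    cigar = "".join(f"{n}{op}" for op, n in cigar_ops)
    return AlignmentResult(matches=matches, columns=columns, cigar=cigar,
                           query_span=q_span, target_span=t_span,
                           score=alignment.score)


def global_align(query: str, target: str) -> AlignmentResult:
    """End-to-end alignment; gaps at either end count as columns."""
    alignment = next(iter(_aligner("global").align(query.upper(), target.upper())))
    result = _summarise(alignment, query, target)
    # make terminal gaps explicit in the column count
    blocks = alignment.aligned
    lead_q = blocks[0][0][0] if len(blocks[0]) else len(query)
    lead_t = blocks[1][0][0] if len(blocks[1]) else len(target)
    tail_q = len(query) - (blocks[0][-1][1] if len(blocks[0]) else 0)
    tail_t = len(target) - (blocks[1][-1][1] if len(blocks[1]) else 0)
    extra = lead_q + lead_t + tail_q + tail_t
    if extra:
        cigar = result.cigar
        if lead_q or lead_t:
            cigar = (f"{lead_q}I" if lead_q else "") + \
                    (f"{lead_t}D" if lead_t else "") + cigar
        if tail_q or tail_t:
            cigar = cigar + (f"{tail_q}I" if tail_q else "") + \
                    (f"{tail_t}D" if tail_t else "")
        result = AlignmentResult(
            matches=result.matches, columns=result.columns + extra,
            cigar=cigar, query_span=result.query_span,
            target_span=result.target_span, score=result.score)
    return result


def local_align(query: str, target: str) -> AlignmentResult:
    """Best-scoring local alignment; unaligned flanks are ignored."""
    alignment = next(iter(_aligner("local").align(query.upper(), target.upper())))
    return _summarise(alignment, query, target)


def identity_percent(matches: int, length: int) -> float:
    return 100.0 * matches / length if length else 0.0
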