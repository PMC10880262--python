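"""Pairwise alignment primitives shared across the pipeline.

Thin wrappers around edlib.  Conventions used everywhere:

* identity = 100 * matched columns / total alignment columns, gaps counted
  as columns (the BLAST convention);
* cigar ops are extended ('=', 'X', 'I', 'D'); with ``align(query, target)``
  an 'I' consumes only the query (base absent from the target) and a 'D'
  consumes only the target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIG = re.compile(r"(\d+)([=XID])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def cigar_identity(cigar: str) -> float:
    """Percent identity from an extended cigar (gap-inclusive columns)."""
    matched = columns = 0
    for n, op in parse_cigar(cigar):
        columns += n
        if op == "=":
            matched += n
    return 100.0 * matched / columns if columns else 0.0


@dataclass(frozen=True)
class Alignment:
    """Result of aligning a query (consensus) against a target window."""

    target_start: int  # 0-based half-open on the target
    target_end: int
    edit_distance: int
    cigar: str

    @property
    def identity(self) -> float:
        return cigar_identity(self.cigar)


def global_align(query: str, target: str) -> Alignment:
    """End-to-end (Needleman-Wunsch) alignment of two sequences."""
    res = edlib.align(query.upper(), target.upper(), mode="NW", task="path")
    return Alignment(0, len(target), res["editDistance"], res["cigar"])


def infix_align(query: str, target: str, max_edits: int = -1) -> Alignment | None:
    """Semi-global alignment: query anywhere inside target, leftmost best hit.

    Returns ``None`` when no placement is within ``max_edits`` (-1: unbounded).
    """
    res = edlib.align(query.upper(), target.upper(), mode="HW", task="path", k=max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = min(res["locations"])  # leftmost of the equally best placements
    return Alignment(start, end + 1, res["editDistance"], res["cigar"])


def tile_query(
    seq: str,
    query: str,
    max_edits: int,
    min_identity: float = 0.0,
) -> list[tuple[int, int, Alignment]]:
    """Tile ``query`` along ``seq`` left to right by semi-global alignment.

    Emits non-overlapping placements (start, end, alignment) in order.
    Placements truncated by the sliding window are re-anchored at their
    true start before acceptance, so hits immediately after an insertion
    are not degraded.  Regions where no placement stays within
    ``max_edits`` (or ``min_identity``) are skipped.
    """
    seq = seq.upper()
    L = len(query)
    slack = max(20, int(0.35 * L))
    step = max(20, L // 3)
    n = len(seq)
    out: list[tuple[int, int, Alignment]] = []
    pos = 0
    while pos + L // 2 <= n:
        w_end = min(pos + L + slack, n)
        aln = infix_align(query, seq[pos:w_end], max_edits=max_edits)
        if aln is None and w_end < n:
            w_end = min(pos + 2 * L, n)
            aln = infix_align(query, seq[pos:w_end], max_edits=max_edits)
        if aln is None:
            pos += step
            continue
        if pos + aln.target_end >= w_end - 2 and aln.target_start > 0 and w_end < n:
            pos = pos + aln.target_start  # truncated at window edge: re-anchor
            continue
        start, end = pos + aln.target_start, pos + aln.target_end
        if aln.identity >= min_identity and end - start >= L // 2:
            out.append((start, end, aln))
            pos = end
        else:
            pos += step
    return out


def mismatch_proportion(a: str, b: str) -> float:
    """Proportion of differing alignment columns between two sequences.

    Substitutions and gap columns both count as differences; used as the
    observed p feeding the Jukes-Cantor distance.
    """
    aln = global_align(a, b)
    return 1.0 - cigar_identity(aln.cigar) / 100.0


def walk_columns(cigar: str):
    """Yield (query_pos, target_pos, op) per alignment column.

    For 'I' columns target_pos is the position *before* the gap (left
    flank); symmetrically for 'D' columns and query_pos.  Positions are
    0-based.
    """
    q = t = 0
    for n, op in parse_cigar(cigar):
        for _ in range(n):
            if op in "=X":
                yield q, t, op
                q += 1
                t += 1
            elif op == "I":  # query base absent from target
                yield q, max(t - 1, 0), op
                q += 1
            else:  # 'D': target base absent from query
                yield max(q - 1, 0), t, op
                t += 1
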