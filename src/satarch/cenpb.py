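"""CENP-B box location, intact/variant classification, and variant clustering.

The CENP-B box is a 17-bp motif inside MiSat-family monomers that is bound
by the CENP-B protein; positions 15-17 are essential for binding.  A box
call is *intact* when the observed 17-mer satisfies the IUPAC-degenerate
canonical motif at every position (a mismatch budget is configurable but
defaults to zero, the strictest reading).  Any mismatch at an essential
position is flagged separately.

Variant clustering is exact-sequence grouping of the observed 17-mers with
occurrence counts (grouping at 100% identity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .library import CenpBMotif
from .monomers import MonomerRecord


@dataclass
class BoxCall:
    monomer_index: int
    offset: int  # within the monomer, 0-based
    observed: str  # 17-bp observed window
    intact: bool
    mismatches: list[tuple[int, str, str]]  # (1-based motif pos, motif symbol, observed base)
    essential_hit: bool

    def __post_init__(self) -> None:
        if self.intact and self.mismatches:
            raise ValueError("an intact call cannot carry mismatches")


def _score_window(window: str, motif: CenpBMotif) -> list[tuple[int, str, str]]:
    return [
        (i, motif.sequence[i - 1], window[i - 1])
        for i in range(1, 18)
        if not motif.matches(window[i - 1], i)
    ]


def scan_boxes(
    monomers: list[MonomerRecord],
    motif: CenpBMotif,
    expected_offset: int,
    slack: int = 5,
    max_mismatches: int = 0,
) -> list[BoxCall]:
    """Best motif placement per monomer at the expected offset +- slack.

    ``expected_offset`` comes from the consensus library annotation; the
    slack absorbs indels upstream of the box.  Placements are scored by
    IUPAC-aware mismatch count (fewest wins, leftmost on ties).  Monomers
    shorter than the motif yield no call.
    """
    calls: list[BoxCall] = []
    for m in monomers:
        seq = m.sequence.upper()
        if len(seq) < 17:
            continue
        lo = max(0, expected_offset - slack)
        hi = min(len(seq) - 17, expected_offset + slack)
        if hi < lo:
            continue
        best = None
        for off in range(lo, hi + 1):
            mm = _score_window(seq[off:off + 17], motif)
            if best is None or len(mm) < len(best[1]):
                best = (off, mm)
        off, mm = best
        calls.append(
            BoxCall(
                monomer_index=m.index,
                offset=off,
                observed=seq[off:off + 17],
                intact=len(mm) <= max_mismatches,
                mismatches=mm if len(mm) > max_mismatches else [],
                essential_hit=any(p in motif.essential_positions for p, _c, _o in mm),
            )
        )
    return calls


def intact_density(calls: list[BoxCall]) -> float:
    """Fraction of scanned boxes that are intact."""
    if not calls:
        raise ValueError("no box calls: intact density undefined")
    return sum(c.intact for c in calls) / len(calls)


def cluster_box_variants(calls: list[BoxCall]) -> list[tuple[str, int]]:
    """Group observed 17-mers exactly; counts descending, then lexicographic."""
    counts = Counter(c.observed for c in calls)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
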