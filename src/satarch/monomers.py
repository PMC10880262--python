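"""Monomer decomposition, per-position variation, and array classification.

Arrays are decomposed by consensus-anchored tiling: the class consensus is
aligned semi-globally, left to right, chaining non-overlapping placements.
Monomer lengths may differ from the consensus through indels (this is what
captures 220-mer/250-mer major-satellite length variants).  Identity is
matches / alignment columns with gaps counted as columns, the BLAST
convention.

The repeat period of an array is estimated without any consensus, from the
base-match autocorrelation between the sequence and its shift; the
dominant lag in a 50-400 bp window is reported.

Class assignment is per-array: MiSat-family arrays are labelled by the
best-scoring consensus (120-mer vs 112-mer vs 112-64 dimer, by summed
matched bases), and MaSat arrays are split into homogeneous vs divergent
by the rule "more than 10 monomers below 75% identity to consensus".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import infix_align, tile_query, walk_columns
from .library import ConsensusLibrary, ConsensusUnit, revcomp


@dataclass
class MonomerRecord:
    """One ordered monomer unit of an array."""

    index: int
    start: int  # 0-based half-open on the (forward) input sequence
    end: int
    strand: str
    sat_class: str
    percent_identity: float
    cigar: str  # consensus-as-query extended cigar
    sequence: str
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def differences(self) -> list[tuple[int, str, int]]:
        """Per consensus position variant calls: (position, kind, length).

        kind is 'X' (substitution), 'I' (deletion from the monomer: the
        consensus base is absent) or 'D' (insertion in the monomer, charged
        to the left-flank consensus position).  Runs of I/D are merged.
        """
        calls: list[tuple[int, str, int]] = []
        for q, _t, op in walk_columns(self.cigar):
            if op == "=":
                continue
            if calls and calls[-1][1] == op == "D" and calls[-1][0] == q:
                calls[-1] = (q, op, calls[-1][2] + 1)
            else:
                calls.append((q, op, 1))
        return calls

    def variant_positions(self) -> set[int]:
        """Consensus positions at which this monomer differs."""
        return {q for q, _t, op in walk_columns(self.cigar) if op != "="}


@dataclass
class VariationProfile:
    """Fraction of monomers that differ from consensus at each position."""

    sat_class: str
    fractions: np.ndarray
    n_monomers: int


@dataclass
class ClassCall:
    array_id: str
    label: str
    evidence: dict = field(default_factory=dict)


def decompose(
    sequence: str,
    unit: ConsensusUnit,
    max_divergence: float = 0.40,
    strand: str = "+",
) -> list[MonomerRecord]:
    """Tile the consensus along an array block, left to right.

    Placements with divergence above ``max_divergence`` are rejected (a gap
    is left).  A block shorter than the consensus yields a single record
    flagged partial.  With ``strand='-'`` the reverse complement is
    decomposed and coordinates are mirrored back onto the input sequence.
    """
    seq = sequence.upper()
    if strand == "-":
        inner = decompose(revcomp(seq), unit, max_divergence, "+")
        n = len(seq)
        for rec in inner:
            rec.start, rec.end = n - rec.end, n - rec.start
            rec.strand = "-"
        return inner

    cons = unit.sequence
    L = len(cons)
    max_edits = max(1, int(round(max_divergence * L)))
    records: list[MonomerRecord] = []

    if len(seq) < L:
        aln = infix_align(seq, cons)  # partial block: align the block into the consensus
        identity = aln.identity if aln else 0.0
        records.append(
            MonomerRecord(0, 0, len(seq), "+", unit.sat_class, identity,
                          aln.cigar if aln else "", seq, partial=True)
        )
        return records

    for index, (start, end, aln) in enumerate(tile_query(seq, cons, max_edits)):
        records.append(
            MonomerRecord(index, start, end, "+", unit.sat_class,
                          aln.identity, aln.cigar, seq[start:end])
        )
    return records


def per_position_variation(
    monomers: list[MonomerRecord], unit: ConsensusUnit
) -> VariationProfile:
    """Fraction of monomers whose aligned base differs at each consensus position.

    Indels are charged to the flanking consensus position, keeping the
    profile length fixed at the monomer length.
    """
    full = [m for m in monomers if not m.partial]
    if len(full) < 2:
        raise ValueError("need at least 2 full monomers for a variation profile")
    counts = np.zeros(unit.monomer_length)
    for m in full:
        for q in m.variant_positions():
            counts[q] += 1
    return VariationProfile(unit.sat_class, counts / len(full), len(full))


def estimate_period(
    sequence: str,
    lag_min: int = 50,
    lag_max: int = 400,
    min_z: float = 3.0,
    min_excess: float = 0.02,
    tie_tolerance: float = 0.05,
) -> int | None:
    """Dominant repeat period of a tandem array, by shift-match score.

    score(lag) = fraction of positions i with s[i] == s[i+lag].  The
    period is the smallest lag whose score is within ``tie_tolerance`` of
    the maximal prominence above the median background (multiples of the
    true period score equally in expectation, so smallest-lag wins).
    Returns ``None`` when no lag stands out from the background by at
    least ``min_z`` robust standard deviations and ``min_excess`` in
    absolute match-rate.
    """
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    hi = min(lag_max, len(arr) // 2)
    if hi < lag_min:
        return None
    lags = np.arange(lag_min, hi + 1)
    scores = np.array([np.mean(arr[:-lag] == arr[lag:]) for lag in lags])
    bg = float(np.median(scores))
    sd = 1.4826 * float(np.median(np.abs(scores - bg)))
    peak = float(scores.max())
    if peak - bg < min_excess or (sd > 0 and (peak - bg) / sd < min_z):
        return None
    cand = lags[scores >= bg + (1.0 - tie_tolerance) * (peak - bg)]
    return int(cand.min())


def assign_class(
    array_id: str,
    sequence: str,
    library: ConsensusLibrary,
    identity_floor: float = 70.0,
    max_divergence: float = 0.40,
    divergent_min_monomers: int = 10,
    divergent_identity: float = 75.0,
) -> ClassCall:
    """Assign one satellite class to an (oriented) array sequence.

    Every candidate consensus is tiled over the array; the class whose
    decomposition recovers the most matched bases wins.  MaSat arrays are
    then split: more than ``divergent_min_monomers`` monomers below
    ``divergent_identity`` percent identity makes the array divergent,
    otherwise homogeneous.
    """
    scores: dict[str, float] = {}
    decomps: dict[str, list[MonomerRecord]] = {}
    for cand in library:
        recs = decompose(sequence, cand, max_divergence)
        recs = [r for r in recs if not r.partial]
        decomps[cand.sat_class] = recs
        scores[cand.sat_class] = sum(r.percent_identity / 100.0 * r.length for r in recs)
    best = max(sorted(scores), key=lambda c: scores[c])
    recs = decomps[best]
    mean_identity = float(np.mean([r.percent_identity for r in recs])) if recs else 0.0
    evidence = {
        "scores": scores,
        "n_monomers": len(recs),
        "mean_identity": mean_identity,
    }
    if not recs or mean_identity < identity_floor:
        return ClassCall(array_id, "unclassified", evidence)
    if best == "MaSat":
        n_low = sum(1 for r in recs if r.percent_identity < divergent_identity)
        evidence["n_below_divergent_threshold"] = n_low
        label = "MaSat_divergent" if n_low > divergent_min_monomers else "MaSat_homogeneous"
        return ClassCall(array_id, label, evidence)
    return ClassCall(array_id, best, evidence)
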