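"""Satellite block discovery and array typing on long reads.

``scan_read`` is a deterministic seed-and-extend scanner: each consensus
unit is tiled along the read by repeated semi-global alignment on both
strands, emitting hits above an identity floor (default 70%).  Externally
produced BLAST-tabular hits can be imported instead
(:func:`satarch.io.parse_hits_tabular`) and fed to the same segmentation.

``segment_and_type`` chains hits into satellite blocks, labels internal
non-satellite gaps, and classifies each read as a Type 1 (continuous) or
Type 2 (interspersed) array, recording strand direction switches and the
set of satellite classes present (junction reads carry more than one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import infix_align, tile_query
from .io import HitRecord
from .library import ConsensusLibrary, revcomp
from .simulate import NONSAT_LABEL


@dataclass(frozen=True)
class ScanParams:
    identity_floor: float = 70.0  # percent
    gap_merge_monomers: float = 0.5  # merge same-class hits closer than this
    gap_min: int = 100  # bp; internal gaps at least this long make a read Type2
    min_monomers: int = 2  # hits needed to call a satellite block
    min_scan_unit: int = 60  # short units (telomere) are tandem-extended to this


@dataclass
class SatBlock:
    read_id: str
    start: int
    end: int
    strand: str
    sat_class: str
    n_hits: int
    mean_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArrayAnnotation:
    read_id: str
    read_length: int
    blocks: list[SatBlock]
    gaps: list[tuple[int, int, str]]  # internal non-satellite gaps >= gap_min
    array_type: str
    direction_switch: bool
    composition: dict[str, float]
    junction_classes: set[str]


def _scan_unit(sequence: str, min_len: int) -> tuple[str, int]:
    """Tandem-extend very short units so alignment is informative."""
    if len(sequence) >= min_len:
        return sequence, len(sequence)
    reps = -(-min_len // len(sequence))
    return sequence * reps, len(sequence) * reps


def scan_read(
    read: str,
    library: ConsensusLibrary,
    params: ScanParams | None = None,
    read_id: str = "read",
) -> list[HitRecord]:
    """Tile every consensus unit along the read on both strands.

    Returns maximal non-redundant hits per consensus/strand with identity
    above the floor, sorted by start.  Overlaps between different consensi
    are resolved later, at segmentation.
    """
    params = params or ScanParams()
    read = read.upper()
    hits: list[HitRecord] = []
    max_div = 1.0 - params.identity_floor / 100.0
    for unit in library:
        query_fwd, scan_len = _scan_unit(unit.sequence, params.min_scan_unit)
        for strand, query in (("+", query_fwd), ("-", revcomp(query_fwd))):
            if len(read) < scan_len:
                continue
            k = int(scan_len * max_div)
            # cheap pre-check: skip consensus/strand absent from the read
            if infix_align(query, read, max_edits=k) is None:
                continue
            hits.extend(
                _tile(read, read_id, unit.name, strand, query, scan_len, k, params)
            )
    hits.sort(key=lambda h: (h.read_start, h.read_end, h.ref_name))
    return hits


def _tile(
    read: str, read_id: str, ref_name: str, strand: str,
    query: str, L: int, max_edits: int, params: ScanParams,
) -> list[HitRecord]:
    return [
        HitRecord(read_id, ref_name, start, end, strand, aln.identity)
        for start, end, aln in tile_query(
            read, query, max_edits, min_identity=params.identity_floor
        )
    ]


def _resolve_overlaps(hits: list[HitRecord]) -> list[HitRecord]:
    """Keep the best hit per region: identity, then length, then leftmost."""
    order = sorted(
        hits, key=lambda h: (-h.percent_identity, -(h.read_end - h.read_start), h.read_start)
    )
    accepted: list[HitRecord] = []
    for h in order:
        conflict = False
        for a in accepted:
            ov = min(h.read_end, a.read_end) - max(h.read_start, a.read_start)
            if ov > 0.5 * min(h.length, a.length):
                conflict = True
                break
        if not conflict:
            accepted.append(h)
    accepted.sort(key=lambda h: (h.read_start, h.read_end))
    return accepted


def segment_and_type(
    read_id: str,
    hits: list[HitRecord],
    read_length: int,
    library: ConsensusLibrary,
    params: ScanParams | None = None,
) -> ArrayAnnotation:
    """Chain hits into blocks and classify the read.

    Adjacent same-consensus same-strand hits are merged when separated by
    less than ``gap_merge_monomers`` monomer lengths.  Blocks need at least
    ``min_monomers`` hits.  Internal unexplained gaps of at least
    ``gap_min`` bp become non-satellite blocks and make the read Type 2;
    terminal unannotated margins never do (reads truncate arrays
    arbitrarily).  A strand change between consecutive same-class blocks
    sets ``direction_switch``.
    """
    params = params or ScanParams()
    unit_class = {u.name: u.sat_class for u in library}
    unit_len = {u.name: max(u.monomer_length, params.min_scan_unit) for u in library}

    accepted = _resolve_overlaps(hits)
    blocks: list[SatBlock] = []
    run: list[HitRecord] = []

    def close_run() -> None:
        if len(run) >= params.min_monomers:
            ids = [h.percent_identity for h in run]
            blocks.append(
                SatBlock(
                    read_id, run[0].read_start, run[-1].read_end, run[0].strand,
                    unit_class[run[0].ref_name], len(run), float(np.mean(ids)),
                )
            )
        run.clear()

    for h in accepted:
        if run and (
            h.ref_name != run[-1].ref_name
            or h.strand != run[-1].strand
            or h.read_start - run[-1].read_end
            >= params.gap_merge_monomers * unit_len[h.ref_name]
        ):
            close_run()
        run.append(h)
    close_run()

    gaps: list[tuple[int, int, str]] = []
    for a, b in zip(blocks, blocks[1:]):
        if b.start - a.end >= params.gap_min:
            gaps.append((a.end, b.start, NONSAT_LABEL))

    composition: dict[str, float] = {}
    if read_length > 0:
        sat = 0
        for blk in blocks:
            composition[blk.sat_class] = composition.get(blk.sat_class, 0) + blk.length
            sat += blk.length
        composition = {c: v / read_length for c, v in composition.items()}
        composition[NONSAT_LABEL] = (read_length - sat) / read_length

    direction_switch = False
    last_strand_by_class: dict[str, str] = {}
    for blk in blocks:
        prev = last_strand_by_class.get(blk.sat_class)
        if prev is not None and prev != blk.strand:
            direction_switch = True
        last_strand_by_class[blk.sat_class] = blk.strand

    return ArrayAnnotation(
        read_id=read_id,
        read_length=read_length,
        blocks=blocks,
        gaps=gaps,
        array_type="Type2" if gaps else "Type1",
        direction_switch=direction_switch,
        composition=composition,
        junction_classes={b.sat_class for b in blocks},
    )


def annotate_read(
    read: str, library: ConsensusLibrary, params: ScanParams | None = None,
    read_id: str = "read",
) -> ArrayAnnotation:
    """Convenience: scan then segment one read."""
    hits = scan_read(read, library, params, read_id=read_id)
    return segment_and_type(read_id, hits, len(read), library, params)


def composition_summary(annotations: list[ArrayAnnotation]) -> pd.Series:
    """Cohort base-fraction per label; fractions sum to one."""
    if not annotations:
        raise ValueError("empty cohort")
    totals: dict[str, float] = {}
    grand = 0
    for ann in annotations:
        grand += ann.read_length
        for label, frac in ann.composition.items():
            totals[label] = totals.get(label, 0.0) + frac * ann.read_length
    return pd.Series({k: v / grand for k, v in sorted(totals.items())}, name="fraction")


def read_length_histogram(
    lengths, bin_bp: int = 500
) -> tuple[pd.DataFrame, float | None]:
    """Binned read-length counts (bin floor(length/bin_bp)) and mean length."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]), None
    idx = np.floor(lengths / bin_bp).astype(int)
    uniq, counts = np.unique(idx, return_counts=True)
    df = pd.DataFrame(
        {"bin_start": uniq * bin_bp, "bin_end": (uniq + 1) * bin_bp, "count": counts}
    )
    return df, float(lengths.mean())
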