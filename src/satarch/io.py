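"""Readers and writers for the external formats the pipeline touches.

All coordinates inside the package are 0-based half-open.  The only
boundary where 1-based inclusive coordinates appear is the BLAST tabular
(outfmt 6) dialect, converted on import.  bedGraph output is run-length
encoded; TSV tables round-trip through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HitRecord:
    """One consensus-vs-read alignment hit on a long read."""

    read_id: str
    ref_name: str
    read_start: int  # 0-based half-open on the read
    read_end: int
    strand: str  # '+' or '-'
    percent_identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end):
            raise ValueError(f"invalid hit interval [{self.read_start}, {self.read_end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"identity out of range: {self.percent_identity}")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class LabeledInterval:
    """A labelled interval on a read (e.g. a RepeatMasker annotation)."""

    read_id: str
    start: int
    end: int
    family: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} <= start {self.start} on {self.read_id}")


def parse_hits_tabular(path: str | Path) -> list[HitRecord]:
    """Import BLAST outfmt-6 hits (12 tab-separated columns).

    File coordinates are 1-based inclusive on the query (the long read);
    hits on the minus strand arrive with qstart > qend and are normalized
    so that read_start < read_end with strand '-'.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                identity = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if qstart <= qend:
                start, end, strand = qstart - 1, qend, "+"
            else:
                start, end, strand = qend - 1, qstart, "-"
            hits.append(HitRecord(qid, sid, start, end, strand, identity))
    return hits


def write_hits_tabular(hits: list[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column outfmt-6 dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                qstart, qend = h.read_start + 1, h.read_end
            else:
                qstart, qend = h.read_end, h.read_start + 1
            fh.write(
                "\t".join(
                    [
                        h.read_id, h.ref_name, f"{h.percent_identity:.2f}",
                        str(h.length), "0", "0", str(qstart), str(qend),
                        "1", str(h.length), "0.0", "0",
                    ]
                )
                + "\n"
            )


def parse_repeatmasker_out(path: str | Path) -> list[LabeledInterval]:
    """Parse a RepeatMasker ``.out`` file into labelled intervals.

    Layout: two header lines and a blank line, then whitespace-separated
    columns; query coordinates (columns 5-7) are 1-based inclusive and are
    converted to 0-based half-open.  Column 10 is the repeat family and
    column 11 the repeat class/family string.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    head = " ".join(lines[:2]).lower()
    if len(lines) < 3 or "sw" not in head.split() and "score" not in head:
        raise ValueError(f"{path}: not a RepeatMasker .out header")
    out: list[LabeledInterval] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
        read_id = fields[4]
        start, end = int(fields[5]) - 1, int(fields[6])
        if end <= start:
            raise ValueError(f"{path}:{lineno}: interval end <= start")
        out.append(LabeledInterval(read_id, start, end, family=fields[9], repeat_class=fields[10]))
    return out


def coverage_to_bedgraph(coverage: np.ndarray, ref_id: str) -> list[tuple[str, int, int, float]]:
    """Run-length encode a per-base coverage vector into bedGraph intervals."""
    coverage = np.asarray(coverage)
    if coverage.size == 0:
        return []
    change = np.flatnonzero(np.diff(coverage)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [coverage.size]])
    return [(ref_id, int(s), int(e), float(coverage[s])) for s, e in zip(starts, ends)]


def write_bedgraph(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref_id in tracks:
            for ref, s, e, v in coverage_to_bedgraph(tracks[ref_id], ref_id):
                fh.write(f"{ref}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Inverse of :func:`write_bedgraph` (dense per-base vectors)."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            ref, s, e, v = line.split("\t")
            intervals.setdefault(ref, []).append((int(s), int(e), float(v)))
    out = {}
    for ref, ivs in intervals.items():
        n = max(e for _, e, _ in ivs)
        vec = np.zeros(n)
        for s, e, v in ivs:
            vec[s:e] = v
        out[ref] = vec
    return out


def write_bed(intervals, path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
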