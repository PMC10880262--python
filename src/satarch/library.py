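"""Consensus satellite library and CENP-B box motif handling.

Mouse centromeric/pericentromeric satellite analysis starts from a small
library of consensus repeat units: the 120-bp minor satellite (MiSat120),
its 112-mer and 112-64-dimer variants, the 234-bp major satellite (MaSat),
the 145-146-bp telocentric TLC satellite, and the telomeric (TTAGGG)n
repeat.  Consensus sequences are *inputs*: they are loaded from a FASTA
file whose headers carry a class tag, never hard-coded.  The same applies
to the 17-bp CENP-B box motif, which is supplied as an IUPAC-degenerate
string; only its length (17) and the essential positions 15-17 are fixed
by the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

SAT_CLASSES = ("MiSat120", "MiSat112", "MiSat112_64", "MaSat", "TLC", "Telomere")

#: IUPAC nucleotide codes -> allowed bases.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusUnit:
    """One reference satellite repeat unit.

    ``box_offset`` is the 0-based offset of the CENP-B box window within the
    monomer, or ``None`` for classes without a box.  For the dimeric class,
    ``subunit_lengths`` records the two sub-unit lengths (they sum to
    ``monomer_length``).
    """

    name: str
    sat_class: str
    sequence: str
    box_offset: int | None = None
    subunit_lengths: tuple[int, int] | None = None

    @property
    def monomer_length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.sat_class not in SAT_CLASSES:
            raise ValueError(f"unknown satellite class {self.sat_class!r} for record {self.name!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.name!r}: non-ACGTN symbols {sorted(bad)}")
        if self.subunit_lengths is not None and sum(self.subunit_lengths) != len(self.sequence):
            raise ValueError(f"record {self.name!r}: sub-unit lengths do not sum to monomer length")


@dataclass(frozen=True)
class CenpBMotif:
    """The 17-bp CENP-B box motif with IUPAC degeneracy.

    ``essential_positions`` are 1-based positions within the motif whose
    conservation distinguishes functional boxes; positions 15-17 are always
    included.
    """

    sequence: str
    essential_positions: frozenset[int] = frozenset({15, 16, 17})

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) != 17:
            raise ValueError(f"CENP-B box motif must be 17 bp, got {len(self.sequence)}")
        if not set(self.sequence) <= set(IUPAC):
            raise ValueError("motif contains non-IUPAC symbols")
        pos = frozenset(int(p) for p in self.essential_positions) | {15, 16, 17}
        if not pos <= set(range(1, 18)):
            raise ValueError("essential positions must lie in 1..17")
        object.__setattr__(self, "essential_positions", pos)

    def matches(self, base: str, position: int) -> bool:
        """Whether ``base`` satisfies the motif at 1-based ``position``."""
        return base.upper() in IUPAC[self.sequence[position - 1]]

    def degenerate_positions(self) -> frozenset[int]:
        """1-based positions where the motif allows more than one base."""
        return frozenset(i + 1 for i, s in enumerate(self.sequence) if len(IUPAC[s]) > 1)


@dataclass
class ConsensusLibrary:
    """Named satellite consensus units plus the canonical CENP-B motif."""

    units: dict[str, ConsensusUnit] = field(default_factory=dict)
    motif: CenpBMotif | None = None

    def __iter__(self):
        return iter(self.units.values())

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, name: str) -> ConsensusUnit:
        return self.units[name]

    def add(self, unit: ConsensusUnit) -> None:
        if unit.name in self.units:
            raise ValueError(f"duplicate consensus record {unit.name!r}")
        self.units[unit.name] = unit

    def by_class(self, sat_class: str) -> list[ConsensusUnit]:
        return [u for u in self if u.sat_class == sat_class]

    def classes(self) -> set[str]:
        return {u.sat_class for u in self}


_EXPECTED_LENGTH = {"MiSat120": 120, "MiSat112": 112, "MaSat": 234}


def _parse_header_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value
    return tags


def load_consensus_library(
    path: str | Path,
    motif: CenpBMotif | None = None,
    strict_lengths: bool = False,
) -> ConsensusLibrary:
    """Load a consensus library from FASTA.

    Header grammar: ``>name class=<sat_class> [box_offset=<int>]
    [subunits=<len1>,<len2>]``.  The ``class`` tag is mandatory and must be
    one of the known satellite classes; ``box_offset`` marks the 0-based
    CENP-B box start within MiSat-family monomers.

    With ``strict_lengths`` the fixed-length classes (MiSat120: 120 bp,
    MiSat112: 112 bp, MaSat: 234 bp) must have exactly those lengths.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty consensus FASTA: {path}")
    lib = ConsensusLibrary(motif=motif)
    for rec in records:
        tags = _parse_header_tags(rec.description)
        if "class" not in tags:
            raise ValueError(f"record {rec.id!r}: missing class=<sat_class> header tag")
        sat_class = tags["class"]
        if sat_class not in SAT_CLASSES:
            raise ValueError(f"record {rec.id!r}: unknown satellite class {sat_class!r}")
        seq = str(rec.seq).upper()
        if strict_lengths and sat_class in _EXPECTED_LENGTH and len(seq) != _EXPECTED_LENGTH[sat_class]:
            raise ValueError(
                f"record {rec.id!r}: class {sat_class} expects length "
                f"{_EXPECTED_LENGTH[sat_class]}, got {len(seq)}"
            )
        box_offset = int(tags["box_offset"]) if "box_offset" in tags else None
        subunits = None
        if "subunits" in tags:
            a, _, b = tags["subunits"].partition(",")
            subunits = (int(a), int(b))
        lib.add(ConsensusUnit(rec.id, sat_class, seq, box_offset=box_offset, subunit_lengths=subunits))
    return lib


def write_consensus_library(lib: ConsensusLibrary, path: str | Path) -> None:
    """Write a library back to FASTA with the documented header grammar."""
    with open(path, "w") as fh:
        for unit in lib:
            tags = [f"class={unit.sat_class}"]
            if unit.box_offset is not None:
                tags.append(f"box_offset={unit.box_offset}")
            if unit.subunit_lengths is not None:
                tags.append(f"subunits={unit.subunit_lengths[0]},{unit.subunit_lengths[1]}")
            fh.write(f">{unit.name} {' '.join(tags)}\n{unit.sequence}\n")
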