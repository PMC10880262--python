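"""Synthetic long reads and ChIP/input read sets with known ground truth.

Every downstream stage of the pipeline is validated against data produced
here: tandem satellite arrays with controlled per-monomer divergence,
monomer-length variants, interspersed non-satellite (TE-like) cassettes,
strand direction switches, junction reads, CENP-B boxes with a controlled
intact fraction, and ChIP/input fragment sets with controlled per-class
fold enrichment and phased or unphased nucleosome placement.

The mutation model is deliberately simple: per-base substitutions uniform
over the three alternative bases, single-base indels at an independent
rate, and box windows of "intact" monomers masked from mutation.  Monomers
designated to carry a *variant* box receive one forced substitution inside
the box window (to a base outside the motif's IUPAC set), so the realized
intact fraction equals the requested one exactly.

ChIP fragments are placed by class weight.  Requested folds are quotients
of class fragment fractions between ChIP and input; because fractions must
sum to one, the generator balances the designated background class so that
the expected value of the downstream estimator equals the requested fold
exactly (infinite-depth limit).  Phased placement draws fragment midpoints
from Gaussians centred once per nucleosome period; unphased placement is
uniform.  Input fragments are always uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .library import IUPAC, CenpBMotif, ConsensusLibrary, ConsensusUnit, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
NONSAT_LABEL = "nonsat"
BACKGROUND = "background"


# ---------------------------------------------------------------------------
# synthetic consensus library

def demo_library(seed: int = 73) -> ConsensusLibrary:
    """A synthetic stand-in consensus library with realistic structure.

    Sequences are random but the *relationships* mirror the real satellite
    classes: the 112-mer is the 120-mer minus an 8-bp block; the dimer is
    the 112-mer fused to a diverged 64-mer sub-unit; the CENP-B box sits at
    a fixed offset within every MiSat-family monomer.  Monomer lengths are
    the real ones (120, 112, 112+64, 234, 146 bp, TTAGGG).
    """
    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return bytes(rng.choice(_BASES, n)).decode()

    mi120 = list(rand_seq(120))
    box_offset = 42
    box_realized = rand_seq(17)
    mi120[box_offset:box_offset + 17] = box_realized
    mi120 = "".join(mi120)

    # motif: the realized box with two degenerate (N) positions, 1-based 5 and 11
    motif_seq = list(box_realized)
    motif_seq[4] = "N"
    motif_seq[10] = "N"
    motif = CenpBMotif("".join(motif_seq))

    mi112 = mi120[:96] + mi120[104:]  # 8-bp deletion downstream of the box
    sub64 = list(mi120[56:])
    for pos in rng.choice(64, size=15, replace=False):
        sub64[pos] = _other_base(sub64[pos], rng)
    dimer = mi112 + "".join(sub64)

    lib = ConsensusLibrary(motif=motif)
    lib.add(ConsensusUnit("MiSat120_cons", "MiSat120", mi120, box_offset=box_offset))
    lib.add(ConsensusUnit("MiSat112_cons", "MiSat112", mi112, box_offset=box_offset))
    lib.add(ConsensusUnit("MiSat112_64_cons", "MiSat112_64", dimer,
                          box_offset=box_offset, subunit_lengths=(112, 64)))
    lib.add(ConsensusUnit("MaSat_cons", "MaSat", rand_seq(234)))
    lib.add(ConsensusUnit("TLC_cons", "TLC", rand_seq(146)))
    lib.add(ConsensusUnit("Telomere_cons", "Telomere", "TTAGGG"))
    return lib


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


# ---------------------------------------------------------------------------
# long-read generation

@dataclass(frozen=True)
class Cassette:
    """A non-satellite insert placed after ``position_in_monomers`` monomers."""

    position_in_monomers: int
    length: int
    label: str = NONSAT_LABEL


@dataclass(frozen=True)
class ArraySpec:
    """Recipe for one synthetic satellite array read."""

    sat_class: str
    n_monomers: int
    per_monomer_divergence: float | tuple[float, ...] = 0.0
    indel_rate: float = 0.0
    intact_box_fraction: float = 1.0
    cassettes: tuple[Cassette, ...] = ()
    direction_switch_at: int | None = None
    junction_partner: "ArraySpec | None" = None
    exact_counts: bool = True
    essential_mut_prob: float = 0.5
    seed: int = 0
    read_id: str = "synthetic_read"

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        rates = self.rates()
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("divergence rates must lie in [0, 1]")
        if not 0.0 <= self.intact_box_fraction <= 1.0:
            raise ValueError("intact_box_fraction must lie in [0, 1]")
        for cas in self.cassettes:
            if not 0 <= cas.position_in_monomers <= self.n_monomers:
                raise ValueError(
                    f"cassette position {cas.position_in_monomers} beyond array of "
                    f"{self.n_monomers} monomers"
                )

    def rates(self) -> tuple[float, ...]:
        if isinstance(self.per_monomer_divergence, (int, float)):
            return (float(self.per_monomer_divergence),) * self.n_monomers
        rates = tuple(float(r) for r in self.per_monomer_divergence)
        if len(rates) != self.n_monomers:
            raise ValueError("per-monomer rate list length != n_monomers")
        return rates


@dataclass
class MonomerTruth:
    index: int
    start: int
    end: int
    strand: str
    sat_class: str
    n_substitutions: int
    n_insertions: int
    n_deletions: int
    box_intact: bool | None  # None when the class carries no box

    @property
    def identity(self) -> float:
        """Generative percent identity (gap-inclusive columns)."""
        cons_len = self.end - self.start - self.n_insertions + self.n_deletions
        columns = cons_len + self.n_insertions
        matches = cons_len - self.n_substitutions - self.n_deletions
        return 100.0 * matches / columns

    @property
    def divergence(self) -> float:
        return 100.0 - self.identity


@dataclass
class BlockTruth:
    start: int
    end: int
    label: str  # sat_class or a cassette label
    strand: str | None  # None for non-satellite


@dataclass
class ReadTruth:
    read_id: str
    length: int
    blocks: list[BlockTruth]
    monomers: list[MonomerTruth]
    array_type: str  # Type1 | Type2
    direction_switch: bool
    junction_classes: set[str]

    def intact_fraction(self) -> float:
        flags = [m.box_intact for m in self.monomers if m.box_intact is not None]
        if not flags:
            raise ValueError("no box-bearing monomers in truth")
        return sum(flags) / len(flags)


def _mutate_monomer(
    unit: ConsensusUnit,
    rate: float,
    indel_rate: float,
    box_state: bool | None,
    motif: CenpBMotif | None,
    rng: np.random.Generator,
    exact_counts: bool,
    essential_mut_prob: float,
) -> tuple[str, int, int, int]:
    """Return (sequence, n_sub, n_ins, n_del) for one mutated monomer copy."""
    seq = list(unit.sequence)
    L = len(seq)
    box_window = set()
    if unit.box_offset is not None and box_state is not None:
        box_window = set(range(unit.box_offset, unit.box_offset + 17))

    mutable = [i for i in range(L) if i not in box_window] if box_state else list(range(L))

    n_sub = round(rate * L) if exact_counts else int(rng.binomial(L, rate))
    n_sub = min(n_sub, len(mutable))
    sub_pos = rng.choice(len(mutable), size=n_sub, replace=False) if n_sub else []
    for p in sub_pos:
        i = mutable[p]
        seq[i] = _other_base(seq[i], rng)

    if box_state is False and motif is not None:
        # force at least one disrupting substitution inside the box window
        candidates = sorted(set(range(1, 18)) - motif.degenerate_positions())
        essential = sorted(p for p in candidates if p in motif.essential_positions)
        pool = essential if (essential and rng.random() < essential_mut_prob) else candidates
        mpos = int(pool[rng.integers(len(pool))])  # 1-based within motif
        i = unit.box_offset + mpos - 1
        allowed = IUPAC[motif.sequence[mpos - 1]]
        bad = sorted(set("ACGT") - allowed)
        new = bad[rng.integers(len(bad))]
        seq[i] = new  # guaranteed outside the motif's allowed set
    n_sub = sum(1 for a, b in zip(seq, unit.sequence) if a != b)

    n_indel = round(indel_rate * L) if exact_counts else int(rng.binomial(L, indel_rate))
    n_ins = n_del = 0
    if n_indel:
        pool = [i for i in range(len(seq)) if i not in box_window] if box_state else list(range(len(seq)))
        pos = sorted(rng.choice(len(pool), size=min(n_indel, len(pool)), replace=False),
                     reverse=True)
        for p in pos:
            i = pool[p]
            if rng.random() < 0.5 and len(seq) > 1:
                del seq[i]
                n_del += 1
            else:
                seq.insert(i, "ACGT"[rng.integers(4)])
                n_ins += 1
    return "".join(seq), n_sub, n_ins, n_del


def make_array_read(
    spec: ArraySpec, library: ConsensusLibrary
) -> tuple[str, ReadTruth]:
    """Emit one synthetic long read and its ground truth.

    The read is the ordered concatenation of mutated monomer copies
    (reverse-complemented from ``direction_switch_at`` onward), with
    non-satellite cassettes inserted at the stated monomer positions.  When
    ``junction_partner`` is set, the partner array is generated with its own
    spec and appended, producing a junction read.
    """
    units = library.by_class(spec.sat_class)
    if not units:
        raise ValueError(f"no consensus unit of class {spec.sat_class!r} in library")
    unit = units[0]
    rng = np.random.default_rng(spec.seed)
    rates = spec.rates()

    has_box = unit.box_offset is not None
    box_states: list[bool | None] = [None] * spec.n_monomers
    if has_box:
        k = round(spec.intact_box_fraction * spec.n_monomers)
        intact_idx = set(sorted(rng.permutation(spec.n_monomers)[:k].tolist()))
        box_states = [i in intact_idx for i in range(spec.n_monomers)]

    cassettes_at: dict[int, list[Cassette]] = {}
    for cas in spec.cassettes:
        cassettes_at.setdefault(cas.position_in_monomers, []).append(cas)

    parts: list[str] = []
    blocks: list[BlockTruth] = []
    monomers: list[MonomerTruth] = []
    pos = 0

    def emit_cassettes(idx: int) -> None:
        nonlocal pos
        for cas in cassettes_at.get(idx, []):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, cas.length))
            parts.append(seq)
            blocks.append(BlockTruth(pos, pos + cas.length, cas.label, None))
            pos += cas.length

    def open_block(strand: str) -> BlockTruth:
        blk = BlockTruth(pos, pos, spec.sat_class, strand)
        blocks.append(blk)
        return blk

    current: BlockTruth | None = None
    for i in range(spec.n_monomers):
        if i in cassettes_at:
            current = None
            emit_cassettes(i)
        strand = "-" if (spec.direction_switch_at is not None and i >= spec.direction_switch_at) else "+"
        if current is None or current.strand != strand:
            current = open_block(strand)
        mono, n_sub, n_ins, n_del = _mutate_monomer(
            unit, rates[i], spec.indel_rate, box_states[i], library.motif,
            rng, spec.exact_counts, spec.essential_mut_prob,
        )
        if strand == "-":
            mono = revcomp(mono)
        parts.append(mono)
        monomers.append(
            MonomerTruth(i, pos, pos + len(mono), strand, spec.sat_class,
                         n_sub, n_ins, n_del, box_states[i])
        )
        pos += len(mono)
        current.end = pos
    emit_cassettes(spec.n_monomers)

    junction_classes = {spec.sat_class}
    if spec.junction_partner is not None:
        partner = replace(spec.junction_partner, read_id=spec.read_id)
        pseq, ptruth = make_array_read(partner, library)
        offset = pos
        parts.append(pseq)
        for blk in ptruth.blocks:
            blocks.append(BlockTruth(blk.start + offset, blk.end + offset, blk.label, blk.strand))
        for m in ptruth.monomers:
            m.start += offset
            m.end += offset
            monomers.append(m)
        pos += ptruth.length
        junction_classes |= ptruth.junction_classes

    read = "".join(parts)
    internal_nonsat = any(
        b.strand is None and b.start > 0 and b.end < pos for b in blocks
    )
    truth = ReadTruth(
        read_id=spec.read_id,
        length=len(read),
        blocks=blocks,
        monomers=monomers,
        array_type="Type2" if internal_nonsat else "Type1",
        direction_switch=_has_switch(blocks),
        junction_classes=junction_classes,
    )
    assert truth.blocks[0].start == 0 and truth.blocks[-1].end == len(read)
    return read, truth


def _has_switch(blocks: list[BlockTruth]) -> bool:
    """Strand change between consecutive same-class satellite blocks."""
    by_class: dict[str, list[str]] = {}
    for b in blocks:
        if b.strand is not None:
            by_class.setdefault(b.label, []).append(b.strand)
    return any(
        a != b for strands in by_class.values() for a, b in zip(strands, strands[1:])
    )


def write_reads_fasta(reads: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads.items():
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# ChIP / input simulation

@dataclass
class RefArray:
    """A reference sequence for short-read mapping, with class intervals."""

    name: str
    length: int
    class_intervals: list[tuple[int, int, str]]
    sequence: str | None = None

    @classmethod
    def from_truth(cls, name: str, sequence: str, truth: ReadTruth) -> "RefArray":
        ivs = [(b.start, b.end, b.label if b.strand is not None else BACKGROUND)
               for b in truth.blocks]
        return cls(name, len(sequence), ivs, sequence=sequence)

    @classmethod
    def background(cls, name: str, length: int, seed: int = 0,
                   with_sequence: bool = False) -> "RefArray":
        seq = None
        if with_sequence:
            rng = np.random.default_rng(seed)
            seq = bytes(rng.choice(_BASES, length)).decode()
        return cls(name, length, [(0, length, BACKGROUND)], sequence=seq)

    def class_at(self, pos: int) -> str:
        for s, e, c in self.class_intervals:
            if s <= pos < e:
                return c
        return BACKGROUND


@dataclass(frozen=True)
class ChipSpec:
    """Recipe for one ChIP (or input) fragment set."""

    mark: str  # e.g. CENP-A, H3K9me3, H3K27me3, input
    fold_by_class: dict[str, float] = field(default_factory=dict)
    phased: bool = False
    nucleosome_period_bp: int | None = None
    particle_spacing_monomers: float | None = None
    site_sd_bp: float = 15.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 15.0
    read_length: int = 75
    depth: float = 50.0
    balance_class: str | None = BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if any(v < 0 for v in self.fold_by_class.values()):
            raise ValueError("folds must be >= 0")


@dataclass
class ChipTruth:
    mark: str
    fold_by_class: dict[str, float]  # effective folds incl. balanced background
    phased: bool
    period_by_class: dict[str, int]
    n_fragments: int


@dataclass
class FragmentSet:
    """Simulated MNase fragments per reference, as (start, end) arrays."""

    refs: list[RefArray]
    fragments: dict[str, np.ndarray]
    truth: ChipTruth

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.fragments.values())


def _class_tables(refs: list[RefArray]) -> dict[str, list[tuple[str, int, int]]]:
    tables: dict[str, list[tuple[str, int, int]]] = {}
    for ref in refs:
        for s, e, c in ref.class_intervals:
            tables.setdefault(c, []).append((ref.name, s, e))
    return tables


def make_chip_reads(
    refs: list[RefArray],
    spec: ChipSpec,
    monomer_length_by_class: dict[str, int] | None = None,
) -> FragmentSet:
    """Simulate a ChIP or input fragment set over the given references.

    Fragment counts per class follow a multinomial with class weights
    f_c = fold_c * g_c, where g_c is the class base fraction; the balance
    class (default ``background``) absorbs the remainder so that the
    weights sum to one and the downstream fold estimator is unbiased.
    """
    if not refs:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(spec.seed)
    tables = _class_tables(refs)
    classes = sorted(tables)
    bases = {c: sum(e - s for _, s, e in tables[c]) for c in classes}
    total = sum(bases.values())
    g = {c: bases[c] / total for c in classes}

    is_input = spec.mark.lower() == "input" or not spec.fold_by_class
    if is_input:
        f = dict(g)
        folds = {c: 1.0 for c in classes}
    else:
        folds = {c: float(spec.fold_by_class.get(c, 1.0)) for c in classes}
        f = {c: folds[c] * g[c] for c in classes}
        if spec.balance_class is not None and spec.balance_class in classes:
            others = sum(v for c, v in f.items() if c != spec.balance_class)
            rem = 1.0 - others
            if rem < 0.005:
                raise ValueError(
                    "background class too small to balance the requested folds; "
                    "increase background abundance"
                )
            f[spec.balance_class] = rem
            folds[spec.balance_class] = rem / g[spec.balance_class]
        else:
            z = sum(f.values())
            f = {c: v / z for c, v in f.items()}
            folds = {c: f[c] / g[c] for c in classes}

    n_frags = int(round(spec.depth * total / spec.fragment_length_mean))
    counts = rng.multinomial(n_frags, [f[c] for c in classes])

    period_by_class: dict[str, int] = {}
    ref_len = {r.name: r.length for r in refs}
    mids_by_ref: dict[str, list[np.ndarray]] = {r.name: [] for r in refs}

    for c, n_c in zip(classes, counts):
        if n_c == 0:
            continue
        ivs = tables[c]
        lens = np.array([e - s for _, s, e in ivs])
        cum = np.concatenate([[0], np.cumsum(lens)])
        phase_this = (
            spec.phased and not is_input and c != spec.balance_class
            and (c in spec.fold_by_class or folds[c] > 1.0)
        )
        if phase_this:
            period = spec.nucleosome_period_bp
            if period is None:
                if monomer_length_by_class is None or c not in monomer_length_by_class:
                    raise ValueError(f"no nucleosome period derivable for class {c!r}")
                period = int(round(spec.particle_spacing_monomers * monomer_length_by_class[c]))
            period_by_class[c] = period
            sites = []
            for name, s, e in ivs:
                centers = np.arange(s + period // 2, e, period)
                sites.append(np.column_stack([np.full(centers.size, _ref_index(refs, name)), centers]))
            sites = np.concatenate(sites)
            pick = rng.integers(0, len(sites), n_c)
            ref_idx = sites[pick, 0]
            mids = sites[pick, 1] + rng.normal(0.0, spec.site_sd_bp, n_c)
        else:
            offs = rng.integers(0, cum[-1], n_c)
            iv_idx = np.searchsorted(cum, offs, side="right") - 1
            ref_idx = np.array([_ref_index(refs, ivs[i][0]) for i in iv_idx])
            mids = np.array([ivs[i][1] for i in iv_idx]) + (offs - cum[iv_idx])
        lengths = rng.normal(spec.fragment_length_mean, spec.fragment_length_sd, n_c)
        lengths = np.clip(lengths, spec.read_length, None).round().astype(int)
        starts = np.round(mids - lengths / 2).astype(int)
        for k, ref in enumerate(refs):
            sel = ref_idx == k
            if not sel.any():
                continue
            st = np.clip(starts[sel], 0, None)
            en = np.minimum(st + lengths[sel], ref_len[ref.name])
            st = np.maximum(np.minimum(st, en - spec.read_length), 0)
            mids_by_ref[ref.name].append(np.column_stack([st, en]))

    fragments = {
        name: (np.concatenate(chunks) if chunks else np.empty((0, 2), dtype=int))
        for name, chunks in mids_by_ref.items()
    }
    for name in fragments:
        frag = fragments[name]
        fragments[name] = frag[np.lexsort((frag[:, 1], frag[:, 0]))]
    truth = ChipTruth(spec.mark, folds, spec.phased, period_by_class, n_frags)
    return FragmentSet(refs, fragments, truth)


def _ref_index(refs: list[RefArray], name: str) -> int:
    for i, r in enumerate(refs):
        if r.name == name:
            return i
    raise KeyError(name)


def fragments_to_fastq(
    frag_set: FragmentSet, path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write paired-end reads (read1 forward, read2 reverse) for a fragment set."""
    rl = 75
    qual = "I" * rl
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for ref in frag_set.refs:
            if ref.sequence is None:
                raise ValueError(f"reference {ref.name} has no sequence; cannot emit FASTQ")
            for i, (s, e) in enumerate(frag_set.fragments[ref.name]):
                r1 = ref.sequence[s:s + rl]
                r2 = revcomp(ref.sequence[e - rl:e])
                rid = f"{ref.name}:{s}-{e}:{i}"
                f1.write(f"@{rid}/1\n{r1}\n+\n{qual[:len(r1)]}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{qual[:len(r2)]}\n")
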