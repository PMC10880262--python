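# satarch

Satellite DNA array architecture and chromatin profiling from long reads.

Mouse centromeres are built on tandem arrays of the 120-bp **minor
satellite** (MiSat, the CENP-A kinetochore substrate, with 112-mer and
112–64-dimer length variants), flanked by 234-bp **major satellite**
(MaSat, H3K9me3 heterochromatin) and 145–146-bp telocentric **TLC**
repeats. `satarch` characterizes these arrays read-by-read in long-read
data and quantifies the chromatin assembled on them from paired-end
ChIP/input sequencing. It is aimed at repeat and centromere biologists who
want a scriptable, tested alternative to ad-hoc BLAST/IGV workflows — and
it ships a synthetic-data generator that gives every analysis stage a
recoverable ground truth.

## What it computes

* **Array discovery and typing** — consensus units are tiled along each
  read on both strands by seed-and-extend semi-global alignment (edlib)
  with an identity floor (default 70%); hits are chained into satellite
  blocks. A read is *Type 1* (continuous) or *Type 2* (interrupted by an
  internal non-satellite gap ≥ 100 bp, typically a transposable element);
  strand flips between same-class blocks are flagged as direction
  switches. BLAST outfmt-6 hits and RepeatMasker `.out` annotations can
  be imported for real data.
* **Monomer decomposition** — consensus-anchored tiling splits each array
  into ordered monomers with percent identity defined as
  `100 · matches / alignment columns` (gaps count as columns); indels
  yield length-variant monomers (220-mer/250-mer MaSat variants).
  Per-position variation profiles, a consensus-free repeat-period
  estimator (dominant shift-match lag in 50–400 bp), and per-array class
  assignment, including the divergent-MaSat rule (> 10 monomers below 75%
  identity ⇒ divergent).
* **CENP-B boxes** — the 17-bp CENP-B box motif (IUPAC-degenerate,
  essential positions 15–17) is scanned at its expected monomer offset;
  boxes are *intact* (zero mismatches at non-degenerate positions) or
  *variant*; variants are clustered exactly with counts.
* **Phylogeny** — neighbor-joining trees of monomers from Jukes–Cantor
  distances, `d = −(3/4)·ln(1 − 4p/3)`, with a clade-partition check for
  box/no-box separation.
* **Chromatin** — fragment-level fold enrichment
  `E_c = (f_c^ChIP) / (f_c^input)` per satellite class (fractions of
  mapped fragments), per-side enrichment on junction reads, nucleosome
  phasing from the autocorrelation of fragment-midpoint density
  (period + score in [0, 1]), and modal particle spacing in monomer
  units.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/05_chip_enrichment.py` simulates CENP-A ChIP/input over
three 120-mer MiSat arrays with a generator fold of 60 and prints:

```
CENP-A on MiSat120 arrays (generator fold 60):
     label  chip_fraction  input_fraction   fold  n_arrays  defined
  MiSat120          0.852           0.014 60.221         3     True
background          0.148           0.986  0.150         1     True

Per-side folds at minor-major junctions (truth 44 / 2.7) ...
 junction_type     side  fold  n_refs
MaSat-MiSat120    MaSat  2.69       3
MaSat-MiSat120 MiSat120 43.86       3
```

85% of ChIP fragments versus 1.4% of input fragments fall on MiSat, an
input-normalized fold of 60.2 — the estimator recovers the simulated
enrichment; junction sides recover 43.9 and 2.7, the minor-satellite
kinetochore signal and its local spreading onto the adjacent major
satellite. `examples/06_nucleosome_phasing.py` prints the phased/unphased
contrast (period 234 bp, score 0.98 vs score 0.06) and a CENP-A particle
spacing of 2 monomer units.

A full synthetic run (`satarch demo`, or `python -m satarch.cli demo`)
writes block BEDs, monomer/box/enrichment/phasing tables, newick trees,
and a JSON run report.

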