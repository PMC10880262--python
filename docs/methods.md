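# Methods

## Scope and model

`satarch` treats a long read as an ordered sequence of satellite blocks
(minor satellite 120/112/112–64-dimer, major satellite 234-mer, TLC
145–146-mer, telomeric hexamer) and non-satellite gaps. All coordinates
are 0-based half-open; 1-based inclusive coordinates exist only at the
BLAST-tabular import boundary. Consensus sequences and the CENP-B box
motif are inputs loaded from FASTA/config — the package asserts only
structural facts (monomer lengths, the 17-bp motif length, essential
positions 15–17) and ships a deterministic *synthetic* consensus library
(`simulate.demo_library`) whose sequences are random but whose
relationships are realistic: the 112-mer is the 120-mer minus an 8-bp
block, the dimer is the 112-mer fused to a diverged 64-mer, and every
MiSat-family unit carries the box at a fixed offset.

## Array discovery

The scanner tiles each consensus along the read on both strands by
repeated semi-global (infix) alignment, implemented with edlib. Tiling is
leftmost-anchored: a candidate window of 1.35 monomer lengths is tried
first, a 2-monomer window as fallback, and placements truncated by the
window edge are re-anchored at their true start so hits immediately after
an insertion are not degraded. Hits need identity ≥ `identity_floor`
(default 70%, playing the role of the BLAST e-value/identity threshold in
the original workflow; the scanner has no word-size parameter). Units
shorter than 50 bp (telomere) are tandem-extended to a 60-bp scan unit.

Segmentation resolves overlapping hits greedily (identity, then length,
then leftmost; conflict = overlap > 50% of the shorter hit), merges
same-consensus same-strand neighbours closer than 0.5 monomer, and
requires ≥ 2 hits per block — one noisy hit is not an array. Internal
gaps ≥ `gap_min` (default 100 bp, below the smallest annotated TE
fragments) become non-satellite blocks and make the read Type 2; terminal
unannotated margins never do, because reads truncate arrays arbitrarily.

## Monomer analysis

Identity is matches / alignment columns with gaps counted as columns
(BLAST convention; the divergent-MaSat rule is therefore gap-inclusive,
configurable). Decomposition tolerates divergence up to `max_divergence`
(default 0.40, matching the tandem-repeat decomposition tolerance used in
the original workflow); worse placements become gaps. Per-position
variation charges substitutions and deletions to their consensus
position and insertions to the left-flank position, keeping profile
length fixed. The dimeric class is decomposed at the 176-bp dimer frame.

The period estimator computes `score(lag) = mean(s[i] == s[i+lag])` over
lags 50–400 bp. Multiples of the true period score equally in
expectation, so the reported period is the *smallest* lag within 5% of
the maximal prominence above the median background — a deterministic tie
rule rather than a bare argmax. "No period" requires the peak to clear
the background by 3 robust (MAD-based) standard deviations *and* by an
absolute match-rate excess of 0.02; with ~350 background lags the pure
3-SD rule alone would fire on random sequence too often.

## CENP-B boxes

The best motif placement per monomer is searched at the consensus box
offset ± 5 bp (absorbing upstream indels), scored by IUPAC-aware
mismatches. "Intact" is the strictest reading — zero mismatches at
non-degenerate positions — with `max_box_mismatch` available to relax it.
Variant clustering is exact-sequence grouping (clustering at identity
1.0 collapses to deduplication with counts).

## Phylogeny

Pairwise p-distances come from global alignment (mismatch + gap columns
over total columns), corrected with Jukes–Cantor; saturated pairs
(p ≥ 0.75) are capped at a configurable maximum with a warning.
Neighbor joining is the standard Saitou–Nei algorithm with the
Q-criterion, deterministic tie-breaks (lexicographically smallest
representative-label pair), negative branch lengths clamped to zero, and
unrooted newick output with a trifurcating root. NJ is consistent on
additive matrices, which the test suite exercises against randomly
generated additive trees and against an independent implementation.
Class-level trees subsample 30 monomers per class under a fixed seed.

## Chromatin

Fragments (MNase mononucleosome units), not reads, are the unit of
coverage and counting. Enrichment is the quotient of class
fragment-count fractions, ChIP over input, assigned by fragment midpoint;
a class absent from input is flagged undefined rather than infinite.
Junction reads get per-side folds with sides shorter than two monomers
excluded. Multi-mapping within near-identical arrays is resolved by a
deterministic best-placement tie-break (lowest reference index,
leftmost); positional estimates inside perfect tandem repeats are
therefore collapsed onto the leftmost copy — a documented limitation that
does not affect class-level fractions.

Phasing is scored on *fragment-midpoint (dyad) density* (lightly
smoothed, σ = 15 bp), not span coverage: span coverage carries a
fragment-length autocorrelation envelope at lags below ~150 bp that both
masks and mimics nucleosome periodicity, while dyad density is white
under the unphased null. The score is the normalized autocovariance peak
over lags 50–400 bp, `(ac(T) − median)/(ac(0) − median)` clipped to
[0, 1]; below 0.3 the array is called unphased. Simulated phased
placement scores > 0.9 and unphased < 0.1 across seeds, comfortably
bracketing the 0.3 threshold. Particle spacing calls peaks (median +
1·MAD after smoothing) on the same dyad track and reports the modal
inter-peak distance in rounded monomer units.

## Synthetic data

The generator emulates: tandem arrays with per-monomer substitution
rates (uniform over the three alternative bases) and single-base indels;
controlled intact-box fractions — exactly `round(f·n)` monomers keep an
unmutated box window, and each designated variant receives one forced
substitution to a base outside the motif's allowed set, so the realized
fraction equals the request exactly; TE-like random cassettes; strand
switches; junction reads; and ChIP/input fragment sets. By default
substitution counts are exact (`round(rate·L)`), making divergence maxima
reproducible; Binomial sampling is available (`exact_counts=False`).

ChIP fragments are multinomial across classes with weight
`fold_c · (class base fraction)`; because fractions must sum to one, the
designated background class absorbs the remainder, which makes the
enrichment estimator unbiased for the requested folds in the
infinite-depth limit. This requires background abundance well above the
fold-weighted satellite abundance (the generator errors otherwise) —
mirroring real ChIP, where enriched targets are a small genome fraction.
Fragment lengths are Gaussian 150 ± 15 bp (MNase mononucleosomes), reads
paired-end 75 bp, default depth 50×. Phased placement draws midpoints
from Gaussians (SD 15 bp) centred once per nucleosome period; input is
always uniform.

What the generator does **not** model: long-read sequencing error beyond
substitutions/indels (HiFi accuracy makes this secondary), PCR
duplicates, GC or mappability bias, chromatin accessibility structure in
the input, or recombination-driven higher-order repeat structure.
Passing tests therefore demonstrate estimator correctness under the
stated generative model, not robustness to every artifact of real
libraries.

## Problem sizes and defaults

Test and demonstration runs use desk-scale sizes chosen to keep sampling
error well inside the assertion tolerances: arrays of 20–200 monomers,
cohorts of ~100 reads, three arrays per enrichment condition, 50×
fragment depth, and backgrounds large enough to balance the requested
folds (1 Mb for fold 60, 300–800 kb otherwise). Headline-number
reproduction from the original ~25× PacBio dataset and real ChIP-seq is
out of scope; real data enter through the BLAST/RepeatMasker/SAM
importers.

## Known limitations

* Per-read annotation only; no assembly of reads into chromosome-scale
  arrays.
* The scanner requires a roughly full monomer to seed a hit, so terminal
  partial monomers are left as unannotated margins.
* Class assignment is per-array; junction reads are classified by their
  dominant class, with per-side analysis delegated to the junction path.
* The phasing score is a package-defined statistic; its absolute scale is
  calibrated against the generator, not against any published metric.
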