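"""Nucleosome phasing and particle spacing from fragment coverage.

H3K9me3 nucleosomes placed once per 234-bp major-satellite monomer give a
strong phasing score with the monomer length as the dominant period;
unphased CENP-A placement scores near zero.  CENP-A placed once per two
120-bp minor-satellite monomers yields a modal particle spacing of 2
monomer units.
"""

from satarch import midpoint_density, particle_spacing, phasing
from satarch.simulate import (
    ArraySpec, ChipSpec, RefArray, demo_library, make_array_read, make_chip_reads,
)

library = demo_library()

seq, truth = make_array_read(ArraySpec("MaSat", 100, 0.02, seed=7, read_id="ma"),
                             library)
refs = [RefArray.from_truth("ma", seq, truth)]
for phased in (True, False):
    fs = make_chip_reads(
        refs,
        ChipSpec("H3K9me3" if phased else "CENP-A", {"MaSat": 3.5}, phased=phased,
                 nucleosome_period_bp=234, seed=8 if phased else 9,
                 balance_class=None))
    p = phasing(midpoint_density(fs)["ma"], monomer_length=234)
    label = "phased" if phased else "unphased"
    print(f"{label:>9}: period={p.period} bp  score={p.score:.2f}  "
          f"called {'phased' if p.phased else 'unphased'}")

seq, truth = make_array_read(ArraySpec("MiSat120", 100, 0.02, seed=10,
                                       read_id="mi"), library)
mrefs = [RefArray.from_truth("mi", seq, truth)]
chip = make_chip_reads(
    mrefs,
    ChipSpec("CENP-A", {"MiSat120": 40.0}, phased=True,
             particle_spacing_monomers=2, seed=11, balance_class=None),
    monomer_length_by_class={"MiSat120": 120})
spacing = particle_spacing(midpoint_density(chip)["mi"], 120)
print(f"CENP-A particle spacing on MiSat: {spacing} monomer units "
      "(one chromatin particle per two 120-bp monomers)")
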