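"""Input-normalized ChIP enrichment on satellite arrays and junctions.

Simulates CENP-A ChIP and input fragments over three 120-mer minor-
satellite arrays (generator fold 60, the centromeric mark's maximum on
this class) plus background, and over minor-major junction reads (folds
44 and 2.7 per side).  The estimator is the quotient of class fragment
fractions, ChIP over input; a fold of 1 means no enrichment.
"""

from satarch import fold_enrichment, junction_profile
from satarch.simulate import (
    ArraySpec, ChipSpec, RefArray, demo_library, make_array_read, make_chip_reads,
)

library = demo_library()

refs = [RefArray.background("bg", 1_000_000, seed=1)]
for i in range(3):
    seq, truth = make_array_read(
        ArraySpec("MiSat120", 40, 0.02, seed=10 + i, read_id=f"mi{i}"), library)
    refs.append(RefArray.from_truth(f"mi{i}", seq, truth))
chip = make_chip_reads(refs, ChipSpec("CENP-A", {"MiSat120": 60.0}, seed=2))
inp = make_chip_reads(refs, ChipSpec("input", seed=3))
df = fold_enrichment(chip, inp)
print("CENP-A on MiSat120 arrays (generator fold 60):")
print(df.round(3).to_string(index=False))

jrefs = [RefArray.background("bg", 800_000, seed=4)]
for i in range(3):
    seq, truth = make_array_read(
        ArraySpec("MiSat120", 30, 0.02, seed=20 + i, read_id=f"j{i}",
                  junction_partner=ArraySpec("MaSat", 20, 0.02, seed=30 + i)),
        library)
    jrefs.append(RefArray.from_truth(f"j{i}", seq, truth))
jchip = make_chip_reads(jrefs, ChipSpec("CENP-A", {"MiSat120": 44.0, "MaSat": 2.7},
                                        seed=5))
jinp = make_chip_reads(jrefs, ChipSpec("input", seed=6))
print("\nPer-side folds at minor-major junctions (truth 44 / 2.7) — the "
      "major-satellite side shows the local CENP-A spreading signal:")
print(junction_profile(jchip, jinp, {"MiSat120": 120, "MaSat": 234})
      .round(2).to_string(index=False))
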