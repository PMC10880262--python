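"""Coverage, enrichment, phasing, spacing, junctions, and the mappers."""

import numpy as np
import pytest

from satarch.chromatin import (
    CoverageTrack,
    class_fragment_counts,
    coverage_from_fragments,
    fold_enrichment,
    fragments_from_sam,
    junction_profile,
    map_fragments,
    midpoint_density,
    particle_spacing,
    phasing,
)
from satarch.simulate import (
    ArraySpec,
    ChipSpec,
    ChipTruth,
    FragmentSet,
    RefArray,
    fragments_to_fastq,
    make_array_read,
    make_chip_reads,
)


def frag_set(ref, frags):
    truth = ChipTruth("test", {}, False, {}, len(frags))
    return FragmentSet([ref], {ref.name: np.array(frags).reshape(-1, 2)}, truth)


class TestCoverage:
    def test_single_fragment_increments_span(self):
        ref = RefArray("r", 400, [(0, 400, "MaSat")])
        tracks = coverage_from_fragments(frag_set(ref, [(100, 250)]))
        cov = tracks["r"].coverage
        assert cov[99] == 0 and cov[100] == 1 and cov[249] == 1 and cov[250] == 0

    def test_conservation_of_fragment_counts(self, library):
        """Class counts sum to the total mapped fragments on both tracks."""
        seq, truth = make_array_read(
            ArraySpec("MaSat", 40, 0.02, seed=1, read_id="a"), library)
        refs = [RefArray.background("bg", 60_000, seed=2),
                RefArray.from_truth("a", seq, truth)]
        for spec in (ChipSpec("mark", {"MaSat": 2.0}, seed=3),
                     ChipSpec("input", seed=4)):
            fs = make_chip_reads(refs, spec)
            counts = class_fragment_counts(fs)
            assert counts["count"].sum() == fs.n_fragments


class TestFoldEnrichment:
    def test_fraction_quotient(self):
        ref = RefArray("r", 1000, [(0, 500, "MiSat120"), (500, 1000, "background")])
        chip = frag_set(ref, [(i, i + 100) for i in range(0, 300, 2)]
                        + [(i, i + 100) for i in range(600, 750, 2)])
        inp = frag_set(ref, [(i, i + 100) for i in range(0, 300, 4)]
                       + [(i, i + 100) for i in range(600, 900, 1)])
        df = fold_enrichment(chip, inp).set_index("label")
        f = df.loc["MiSat120", "chip_fraction"]
        g = df.loc["MiSat120", "input_fraction"]
        assert df.loc["MiSat120", "fold"] == pytest.approx(f / g)

    def test_null_case_fold_one(self):
        ref = RefArray("r", 1000, [(0, 500, "MaSat"), (500, 1000, "background")])
        frags = [(i, i + 120) for i in range(0, 880, 10)]
        df = fold_enrichment(frag_set(ref, frags), frag_set(ref, frags)).set_index("label")
        assert df.loc["MaSat", "fold"] == 1.0

    def test_zero_input_fraction_flagged_not_infinite(self):
        ref = RefArray("r", 1000, [(0, 500, "MaSat"), (500, 1000, "background")])
        chip = frag_set(ref, [(10, 130), (700, 820)])
        inp = frag_set(ref, [(700, 820), (800, 920)])
        df = fold_enrichment(chip, inp).set_index("label")
        assert not df.loc["MaSat", "defined"]
        assert np.isnan(df.loc["MaSat", "fold"])

    def test_scale_invariance_under_depth_doubling(self, library):
        seq, truth = make_array_read(
            ArraySpec("MaSat", 40, 0.02, seed=5, read_id="a"), library)
        refs = [RefArray.background("bg", 80_000, seed=6),
                RefArray.from_truth("a", seq, truth)]
        inp = make_chip_reads(refs, ChipSpec("input", seed=7))
        e = {}
        for depth in (25.0, 50.0):
            chip = make_chip_reads(refs, ChipSpec("m", {"MaSat": 3.0}, depth=depth, seed=8))
            e[depth] = fold_enrichment(chip, inp).set_index("label").loc["MaSat", "fold"]
        assert e[50.0] == pytest.approx(e[25.0], rel=0.05)


class TestPhasing:
    def test_ideal_comb_scores_near_one(self):
        cov = np.zeros(23_400)
        cov[117::234] = 100.0
        p = phasing(CoverageTrack("r", cov, 100), monomer_length=234)
        assert p.period == 234
        assert p.score > 0.9
        assert p.spacing_monomers == 1

    def test_flat_track_unphased(self):
        p = phasing(CoverageTrack("r", np.full(10_000, 7.0), 100))
        assert not p.phased and p.score == 0.0

    def test_uniform_noise_unphased(self, rng):
        cov = rng.poisson(50, 20_000).astype(float)
        p = phasing(CoverageTrack("r", cov, 100))
        assert not p.phased

    @pytest.mark.parametrize("seed", range(20))
    def test_phased_vs_unphased_separation_across_seeds(self, library, seed):
        """Phased simulations score > 0.5; unphased < 0.3 (20 seeds)."""
        seq, truth = make_array_read(
            ArraySpec("MaSat", 100, 0.02, seed=90, read_id="m"), library)
        refs = [RefArray.from_truth("m", seq, truth)]
        phased = make_chip_reads(
            refs, ChipSpec("H3K9me3", {"MaSat": 3.5}, phased=True,
                           nucleosome_period_bp=234, seed=3000 + seed,
                           balance_class=None))
        sp = phasing(midpoint_density(phased)["m"], monomer_length=234)
        assert sp.phased and sp.score > 0.5 and sp.period == 234
        unphased = make_chip_reads(
            refs, ChipSpec("CENP-A", {"MaSat": 1.0}, phased=False,
                           seed=4000 + seed, balance_class=None))
        su = phasing(midpoint_density(unphased)["m"])
        assert not su.phased and su.score < 0.3


class TestParticleSpacing:
    def test_peaks_every_two_monomers(self):
        cov = np.zeros(12_000)
        for c in range(120, 12_000, 240):
            cov[c - 40:c + 40] += 60.0
        assert particle_spacing(CoverageTrack("r", cov, 50), 120) == 2

    def test_peaks_every_monomer(self):
        cov = np.zeros(12_000)
        for c in range(60, 12_000, 120):
            cov[c - 30:c + 30] += 60.0
        assert particle_spacing(CoverageTrack("r", cov, 120), 120) == 1

    def test_too_few_peaks_undefined(self):
        cov = np.zeros(1_000)
        cov[400:500] = 10.0
        assert particle_spacing(CoverageTrack("r", cov, 120), 120) is None

    def test_generator_spacing_two_recovered(self, library):
        seq, truth = make_array_read(
            ArraySpec("MiSat120", 100, 0.02, seed=10, read_id="mi"), library)
        refs = [RefArray.from_truth("mi", seq, truth)]
        chip = make_chip_reads(
            refs,
            ChipSpec("CENP-A", {"MiSat120": 40.0}, phased=True,
                     particle_spacing_monomers=2, seed=11, balance_class=None),
            monomer_length_by_class={"MiSat120": 120})
        track = midpoint_density(chip)["mi"]
        assert particle_spacing(track, 120) == 2


class TestJunctionProfile:
    def make_junction_refs(self, library, n=3):
        refs = [RefArray.background("bg", 800_000, seed=1)]
        for i in range(n):
            seq, truth = make_array_read(
                ArraySpec("MiSat120", 30, 0.02, seed=40 + i, read_id=f"j{i}",
                          junction_partner=ArraySpec("MaSat", 20, 0.02, seed=50 + i)),
                library)
            refs.append(RefArray.from_truth(f"j{i}", seq, truth))
        return refs

    def test_per_side_folds_recovered(self, library):
        refs = self.make_junction_refs(library)
        chip = make_chip_reads(
            refs, ChipSpec("CENP-A", {"MiSat120": 44.0, "MaSat": 2.7}, seed=60))
        inp = make_chip_reads(refs, ChipSpec("input", seed=61))
        df = junction_profile(chip, inp, {"MiSat120": 120, "MaSat": 234}).set_index("side")
        assert df.loc["MiSat120", "fold"] == pytest.approx(44.0, rel=0.15)
        assert df.loc["MaSat", "fold"] == pytest.approx(2.7, rel=0.15)
        assert (df["junction_type"] == "MaSat-MiSat120").all()

    def test_input_only_run_gives_fold_one(self, library):
        refs = self.make_junction_refs(library)
        a = make_chip_reads(refs, ChipSpec("input", seed=70))
        b = make_chip_reads(refs, ChipSpec("input", seed=71))
        df = junction_profile(a, b, {"MiSat120": 120, "MaSat": 234})
        assert df["fold"].between(0.9, 1.1).all()

    def test_short_side_excluded(self, library):
        refs = [RefArray.background("bg", 100_000, seed=2)]
        seq, truth = make_array_read(
            ArraySpec("MiSat120", 20, 0.02, seed=80, read_id="j",
                      junction_partner=ArraySpec("MaSat", 1, 0.0, seed=81)),
            library)
        refs.append(RefArray.from_truth("j", seq, truth))
        chip = make_chip_reads(refs, ChipSpec("CENP-A", {"MiSat120": 5.0}, seed=82))
        inp = make_chip_reads(refs, ChipSpec("input", seed=83))
        df = junction_profile(chip, inp, {"MiSat120": 120, "MaSat": 234})
        assert "MaSat" not in set(df.get("side", []))


class TestMappers:
    def test_round_trip_through_fastq_mapper(self, tmp_path):
        """On a non-repetitive reference, simulated pairs map back to their
        exact fragment spans.  (On tandem arrays placements collapse onto
        the leftmost copy by the deterministic tie-break, so positional
        round-trips are only meaningful off-repeat.)"""
        ref = RefArray.background("bg", 8_000, seed=1, with_sequence=True)
        fs = make_chip_reads([ref], ChipSpec("input", depth=3.0, seed=2,
                                             balance_class=None))
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        fragments_to_fastq(fs, r1, r2)
        mapped, stats = map_fragments([ref], r1, r2)
        assert stats.mapped >= 0.9 * fs.n_fragments
        assert stats.discarded_insert == 0
        sim = {tuple(f) for f in fs.fragments["bg"]}
        got = {tuple(f) for f in mapped.fragments["bg"]}
        assert len(got & sim) >= 0.9 * len(got)

    def test_sam_import_honours_insert_bounds(self, library, tmp_path):
        ref = RefArray("m", 2_000, [(0, 2_000, "MaSat")])
        sam = tmp_path / "t.sam"
        lines = [
            "@HD\tVN:1.6\tSO:coordinate",
            "@SQ\tSN:m\tLN:2000",
            # concordant pair, insert 150
            "p1\t99\tm\t101\t60\t75M\t=\t176\t150\t" + "A" * 75 + "\t" + "I" * 75,
            "p1\t147\tm\t176\t60\t75M\t=\t101\t-150\t" + "A" * 75 + "\t" + "I" * 75,
            # insert 900: discarded
            "p2\t99\tm\t101\t60\t75M\t=\t926\t900\t" + "A" * 75 + "\t" + "I" * 75,
            "p2\t147\tm\t926\t60\t75M\t=\t101\t-900\t" + "A" * 75 + "\t" + "I" * 75,
        ]
        sam.write_text("\n".join(lines) + "\n")
        fs, stats = fragments_from_sam(sam, [ref])
        assert stats.mapped == 1
        assert stats.discarded_insert == 1
        np.testing.assert_array_equal(fs.fragments["m"], [[100, 250]])
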