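"""Monomer decomposition, variation profiles, period, class assignment."""

import numpy as np
import pytest

from satarch.monomers import (
    assign_class,
    decompose,
    estimate_period,
    per_position_variation,
)
from satarch.library import revcomp
from satarch.simulate import ArraySpec, make_array_read

from conftest import random_dna


def substitute(seq, positions):
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for i in positions:
        out[i] = flip[out[i]]
    return "".join(out)


class TestDecompose:
    def test_exact_copies(self, library):
        cons = library["MiSat120_cons"].sequence
        recs = decompose(cons * 5, library["MiSat120_cons"])
        assert [(r.index, r.start, r.end) for r in recs] == [
            (i, i * 120, (i + 1) * 120) for i in range(5)
        ]
        assert all(r.percent_identity == 100.0 for r in recs)

    def test_six_substitutions_give_identity_95(self, library):
        unit = library["MiSat120_cons"]
        mutated = substitute(unit.sequence, [3, 20, 40, 70, 90, 110])
        recs = decompose(unit.sequence + mutated + unit.sequence, unit)
        assert [round(r.percent_identity, 1) for r in recs] == [100.0, 95.0, 100.0]

    def test_deletion_yields_length_variant_monomer(self, library):
        """A 14-bp deletion produces a 220-mer with the deletion recorded."""
        unit = library["MaSat_cons"]
        copies = [unit.sequence] * 5
        copies[2] = unit.sequence[:100] + unit.sequence[114:]
        recs = decompose("".join(copies), unit)
        assert [r.length for r in recs] == [234, 234, 220, 234, 234]
        kinds = {op for _q, op, _n in recs[2].differences()}
        assert kinds == {"I"}  # consensus bases absent from the monomer
        assert sum(n for _q, _op, n in recs[2].differences()) == 14

    def test_coverage_of_block(self, library):
        read, _ = make_array_read(ArraySpec("MaSat", 30, 0.10, indel_rate=0.01, seed=3),
                                  library)
        recs = decompose(read, library["MaSat_cons"])
        covered = sum(r.length for r in recs)
        assert covered >= 0.9 * len(read)

    def test_reverse_complement_mirrors_records(self, library):
        read, _ = make_array_read(ArraySpec("MaSat", 10, 0.05, seed=4), library)
        fwd = decompose(read, library["MaSat_cons"])
        rev = decompose(revcomp(read), library["MaSat_cons"], strand="-")
        assert len(fwd) == len(rev)
        n = len(read)
        mirrored = sorted((n - r.end, n - r.start) for r in rev)
        assert mirrored == sorted((r.start, r.end) for r in fwd)
        assert sorted(round(r.percent_identity, 6) for r in rev) == sorted(
            round(r.percent_identity, 6) for r in fwd
        )

    def test_block_shorter_than_consensus_is_partial(self, library):
        unit = library["MaSat_cons"]
        recs = decompose(unit.sequence[:150], unit)
        assert len(recs) == 1 and recs[0].partial

    @pytest.mark.parametrize("rate", [0.0, 0.05, 0.10, 0.203])
    def test_mean_identity_tracks_true_divergence(self, library, rate):
        read, truth = make_array_read(
            ArraySpec("MiSat120", 50, rate, seed=int(rate * 1e4) + 1), library)
        recs = decompose(read, library["MiSat120_cons"])
        got = np.mean([r.percent_identity for r in recs])
        assert got == pytest.approx(100 * (1 - rate), abs=1.0)


class TestPerPositionVariation:
    def test_substitution_at_one_position_in_half_the_monomers(self, library):
        unit = library["MiSat120_cons"]
        copies = [unit.sequence] * 10
        for k in range(5):
            copies[k] = substitute(copies[k], [7])
        recs = decompose("".join(copies), unit)
        prof = per_position_variation(recs, unit)
        assert prof.fractions[7] == 0.5
        assert prof.fractions.sum() == 0.5

    def test_identical_monomers_have_zero_profile(self, library):
        unit = library["MiSat120_cons"]
        recs = decompose(unit.sequence * 5, unit)
        prof = per_position_variation(recs, unit)
        assert not prof.fractions.any()

    def test_box_disruption_peaks_inside_box_window(self, library):
        """Variant boxes concentrate variation at the box offsets."""
        unit = library["MiSat120_cons"]
        read, _ = make_array_read(
            ArraySpec("MiSat120", 100, 0.0, intact_box_fraction=0.2, seed=9), library)
        recs = decompose(read, unit)
        prof = per_position_variation(recs, unit)
        box = prof.fractions[unit.box_offset:unit.box_offset + 17]
        assert box.sum() >= 0.8  # the 80% variant monomers each carry >= 1 hit
        outside = np.delete(prof.fractions, range(unit.box_offset, unit.box_offset + 17))
        assert not outside.any()

    def test_profile_mean_matches_mean_identity(self, library):
        read, _ = make_array_read(ArraySpec("MaSat", 40, 0.08, seed=10), library)
        unit = library["MaSat_cons"]
        recs = decompose(read, unit)
        prof = per_position_variation(recs, unit)
        mean_div = 1 - np.mean([r.percent_identity for r in recs]) / 100
        assert prof.fractions.mean() == pytest.approx(mean_div, abs=0.005)


class TestEstimatePeriod:
    def test_exact_tandem_120(self, library):
        read, _ = make_array_read(ArraySpec("MiSat120", 50, seed=1), library)
        assert estimate_period(read) == 120

    @pytest.mark.parametrize("seed", range(5))
    def test_mutated_234_recovered(self, library, seed):
        read, _ = make_array_read(
            ArraySpec("MaSat", 50, 0.02, exact_counts=False, seed=seed), library)
        assert estimate_period(read) == 234

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequence_has_no_period(self, seed):
        rng = np.random.default_rng(seed)
        assert estimate_period(random_dna(8_000, rng)) is None

    def test_brute_force_agreement(self, library):
        """Cross-check: the reported lag maximizes the shift-match score."""
        read, _ = make_array_read(
            ArraySpec("MaSat", 50, 0.02, exact_counts=False, seed=11), library)
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        scores = {lag: float(np.mean(arr[:-lag] == arr[lag:])) for lag in range(50, 401)}
        best = max(scores.values())
        got = estimate_period(read)
        assert scores[got] >= 0.95 * best


class TestAssignClass:
    def test_dimer_array_assigned_dimer_class(self, library):
        read, _ = make_array_read(ArraySpec("MiSat112_64", 20, 0.03, seed=1), library)
        assert assign_class("a", read, library).label == "MiSat112_64"

    def test_masat_divergent_rule_requires_more_than_ten(self, library):
        rates = tuple([0.30] * 12 + [0.02] * 18)
        read, _ = make_array_read(ArraySpec("MaSat", 30, rates, seed=2), library)
        call = assign_class("b", read, library)
        assert call.label == "MaSat_divergent"
        assert call.evidence["n_below_divergent_threshold"] > 10

    def test_masat_few_divergent_monomers_stays_homogeneous(self, library):
        rates = tuple([0.30] * 5 + [0.02] * 25)
        read, _ = make_array_read(ArraySpec("MaSat", 30, rates, seed=3), library)
        assert assign_class("c", read, library).label == "MaSat_homogeneous"

    def test_misat_variants_separated(self, library):
        for cls in ("MiSat120", "MiSat112"):
            read, _ = make_array_read(ArraySpec(cls, 20, 0.03, seed=4), library)
            assert assign_class("d", read, library).label == cls

    def test_random_sequence_unclassified(self, rng):
        from satarch.simulate import demo_library

        library = demo_library()
        assert assign_class("e", random_dna(3_000, rng), library).label == "unclassified"
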