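import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import popgenstat

import indelpoly as ip
from indelpoly import alignment_io as aio, popgen
from indelpoly.dimorphism import HaplogroupPartition

from .conftest import random_alignment
from . import oracles


def make(seqs, ids=None, locus="L"):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return ip.Alignment.from_sequences(locus, ids, seqs)


def halves(a):
    h = a.n // 2
    return HaplogroupPartition(tuple(a.sample_ids[:h]), tuple(a.sample_ids[h:]))


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert ip.nucleotide_diversity(make(["AAAA"] * 3)) == 0.0

    def test_small_worked_example(self):
        # 8 pairwise diffs / 6 pairs / 4 sites
        a = make(["ACGT", "ACGA", "TCGT", "TCGA"])
        assert ip.nucleotide_diversity(a) == pytest.approx(8 / 6 / 4, abs=1e-15)

    def test_matches_hamming_oracle_on_random_fixtures(self, rng):
        for _ in range(20):
            a = random_alignment(rng, int(rng.integers(3, 21)), 500)
            assert ip.nucleotide_diversity(a) == pytest.approx(
                oracles.hamming_pi(a.sequences()), abs=1e-12)

    def test_single_sample_rejected(self):
        a = make(["AAAA", "AAAA"])
        one = ip.Alignment.from_sequences
        with pytest.raises(aio.AlignmentFormatError):
            one("x", ["s"], ["AAAA"])

    def test_all_uncalled_returns_nan(self):
        assert math.isnan(ip.nucleotide_diversity(make(["----", "NNNN"])))


class TestWattersonTheta:
    def test_zero_segregating_sites(self):
        assert ip.watterson_theta(0, 10, 100) == 0.0

    def test_pairwise_harmonic_is_one(self):
        assert ip.watterson_theta(2, 2, 1) == 2.0

    def test_large_sample_harmonic_oracle(self):
        a95 = sum(1.0 / j for j in range(1, 96))
        assert ip.watterson_theta(10, 96, 600) == pytest.approx(10 / a95 / 600, rel=1e-14)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ip.watterson_theta(1, 5, 0)


class TestTajimasD:
    def test_monomorphic_is_undefined(self):
        assert math.isnan(ip.tajimas_d(make(["AAAA"] * 5)))

    def test_matches_independent_formula(self):
        a = make(["ACGT", "ACGA", "TCGT", "TCGA"])
        assert ip.tajimas_d(a) == pytest.approx(
            oracles.textbook_tajimas_d(a.sequences()), abs=1e-12)

    def test_matches_dendropy_on_random_fixtures(self, rng):
        for _ in range(10):
            a = random_alignment(rng, int(rng.integers(4, 15)), 120)
            mat = popgenstat.tajimas_d(dendropy.DnaCharacterMatrix.from_dict(
                dict(zip(a.sample_ids, a.sequences()))))
            assert ip.tajimas_d(a) == pytest.approx(mat, abs=1e-9)


class TestBetweenGroupDxy:
    def test_identical_groups(self):
        a = make(["ACGT"] * 4)
        assert ip.between_group_dxy(a, halves(a)) == 0.0

    def test_single_pair(self):
        a = make(["AAAA", "AAAT"])
        assert ip.between_group_dxy(a, halves(a)) == 0.25

    def test_matches_cross_pair_oracle(self, rng):
        for _ in range(10):
            a = random_alignment(rng, 8, 300)
            p = halves(a)
            assert ip.between_group_dxy(a, p) == pytest.approx(
                oracles.cross_pair_dxy(a.sequences()[:4], a.sequences()[4:]), abs=1e-12)


class TestFixedDivergence:
    def test_constructed_fixed_sites(self):
        x = ["ACGTACGTAC"] * 2
        y = ["TCGTACGAAC"] * 2
        a = make(x + y)
        d, cols, leff = ip.fixed_divergence_dxy(a, halves(a))
        assert list(cols) == [0, 7]
        assert d == pytest.approx(0.2)

    def test_shared_allele_breaks_fixation(self):
        a = make(["ACGT", "ACGT", "TCGT", "ACGT"])
        d, cols, _ = ip.fixed_divergence_dxy(a, halves(a))
        assert list(cols) == [] and d == 0.0

    def test_third_allele_both_groups_fixed_counts(self):
        a = make(["AAAA", "AAAA", "ACAA", "ACAA"])
        mat = a.matrix.copy()
        mat[:2, 1] = ord("G")  # x fixed G, y fixed C at col 1
        a = ip.Alignment("t", a.sample_ids, mat)
        _, cols, _ = ip.fixed_divergence_dxy(a, halves(a))
        assert list(cols) == [1]

    def test_fixed_subset_of_average_differences(self, rng):
        for _ in range(10):
            a = random_alignment(rng, 10, 200)
            p = halves(a)
            masked = ip.mask_fixed_indels(a, p)
            d, _, _ = ip.fixed_divergence_dxy(masked, p)
            assert d <= ip.between_group_dxy(masked, p) + 1e-15

    def test_adding_fixed_column_increments_by_unit(self, rng):
        a = random_alignment(rng, 8, 100)
        p = halves(a)
        d0, cols0, leff = ip.fixed_divergence_dxy(a, p)
        mat = a.matrix.copy()
        free = [c for c in range(100) if c not in set(cols0.tolist())]
        col = free[0]
        mat[:4, col] = ord("A")
        mat[4:, col] = ord("C")
        d1, cols1, _ = ip.fixed_divergence_dxy(
            ip.Alignment("t", a.sample_ids, mat), p)
        assert len(cols1) == len(cols0) + 1
        assert d1 - d0 == pytest.approx(1 / leff, abs=1e-15)


class TestDecomposition:
    @pytest.mark.parametrize("d_xy,expected", [(0.0628, 0.0329), (0.0894, 0.0468)])
    def test_fixed_component_weighting(self, d_xy, expected):
        """2*n1*n2/(n(n-1)) * d_xy for the 10:11 split of 21 accessions."""
        val = ip.fixed_diversity_component(d_xy, 10, 11)
        assert round(val, 4) == expected

    def test_pi_t_equals_direct_diversity(self, rng):
        for _ in range(25):
            a = random_alignment(rng, int(rng.integers(4, 12)), 300,
                                 missing=float(rng.choice([0.0, 0.03])))
            p = halves(a)
            masked = ip.mask_fixed_indels(a, p)
            if aio.effective_length(masked) == 0:
                continue
            dec = ip.decompose_diversity(masked, p, mask=False)
            assert dec.pi_t == pytest.approx(
                ip.nucleotide_diversity(masked), abs=1e-12)
            assert dec.pi_t == pytest.approx(
                dec.pi_h + dec.pi_fixedxy + dec.pi_nonfixedxy, abs=1e-12)

    def test_degenerate_partition_rejected(self):
        a = make(["ACGT"] * 4)
        with pytest.raises(ValueError):
            ip.decompose_diversity(a, HaplogroupPartition(("s0",), ("s1", "s2", "s3")))
            bad = type("P", (), {"x_members": (), "y_members": a.sample_ids})()
            ip.decompose_diversity(a, bad)


class TestSlidingWindows:
    def test_uniform_fixture_windows_near_global(self, rng):
        a = random_alignment(rng, 10, 1000)
        p = halves(a)
        track = ip.sliding_window_track(a, p, window=200, step=100)
        global_pi = ip.nucleotide_diversity(ip.mask_fixed_indels(a, p))
        assert np.nanmax(np.abs(track.pi_values - global_pi)) < 0.15

    def test_window_equal_to_locus_is_global(self, rng):
        a = random_alignment(rng, 8, 300)
        p = halves(a)
        track = ip.sliding_window_track(a, p, window=300, step=300)
        masked = ip.mask_fixed_indels(a, p)
        assert track.pi_values[0] == pytest.approx(ip.nucleotide_diversity(masked))
        d, _, _ = ip.fixed_divergence_dxy(masked, p)
        assert track.dxy_values[0] == pytest.approx(d)

    def test_oversized_window_flagged_single(self, rng):
        a = random_alignment(rng, 6, 50)
        track = ip.sliding_window_track(a, halves(a), window=100, step=10)
        assert track.single_window and len(track.centers) == 1

    def test_dxy_peak_sits_at_junction(self):
        cfg = ip.SyntheticConfig(seed=17)
        a, truth = ip.generate_dimorphic_locus(cfg)
        ev = aio.extract_indels(a, min_size=100)[0]
        from indelpoly.dimorphism import partition_by_indel
        p = partition_by_indel(a, ev)
        track = ip.sliding_window_track(a, p, window=100, step=25, junction=ev)
        peak = track.centers[np.nanargmax(track.dxy_values)]
        assert abs(peak) <= 100
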