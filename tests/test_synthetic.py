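import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

import indelpoly as ip
from indelpoly import alignment_io as aio, dimorphism, popgen, synthetic
from indelpoly.popgen import harmonic_number


class TestDimorphicGenerator:
    def test_zero_amplitude_means_zero_fixed_divergence(self):
        cfg = ip.SyntheticConfig(seed=1, amplitude=0.0, homogenization_p=0.0)
        a, truth = ip.generate_dimorphic_locus(cfg)
        assert truth.fixed_sites == ()
        ev = aio.extract_indels(a, min_size=100)[0]
        p = dimorphism.partition_by_indel(a, ev)
        masked = aio.mask_fixed_indels(a, p)
        d, cols, _ = popgen.fixed_divergence_dxy(masked, p)
        assert d == 0.0 and len(cols) == 0

    def test_truth_record_consistency(self):
        for seed in range(6):
            cfg = ip.SyntheticConfig(seed=seed, homogenization_p=0.3,
                                     suppression_window=200)
            a, truth = ip.generate_dimorphic_locus(cfg)  # verify=True raises on drift
            ev = aio.extract_indels(a, min_size=100)[0]
            assert ev.span == truth.indel_span
            assert ev.presence == truth.presence
            p = dimorphism.partition_by_indel(a, ev)
            masked = aio.mask_fixed_indels(a, p)
            _, cols, _ = popgen.fixed_divergence_dxy(masked, p)
            assert set(cols.tolist()) == set(truth.fixed_columns())

    def test_seed_determinism_bytes(self, tmp_path):
        cfg = ip.SyntheticConfig(seed=99)
        a1, _ = ip.generate_dimorphic_locus(cfg)
        a2, _ = ip.generate_dimorphic_locus(cfg)
        assert a1 == a2
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        ip.write_alignment(a1, p1)
        ip.write_alignment(a2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_first_bin_matches_planted_intensity(self):
        # mean pipeline d_xy over [0,100) ~= mean planted intensity there
        vals = []
        for seed in range(50):
            cfg = ip.SyntheticConfig(seed=seed, amplitude=0.08, decay_scale=300.0,
                                     suppression_window=1000, n1=10, n2=11,
                                     length=4000)
            _, truth = ip.generate_dimorphic_locus(cfg)
            b0 = truth.dxy_by_bin[0]
            vals.append(b0[1] / b0[2])
        expect = 0.08 * np.exp(-np.arange(100) / 300.0).mean()
        n_sites = 50 * 200
        se = math.sqrt(expect / n_sites)
        assert abs(np.mean(vals) - expect) < 3 * se

    def test_effect_size_monotonicity(self):
        means = []
        for amp in (0.0, 0.02, 0.08):
            first = []
            for seed in range(30):
                cfg = ip.SyntheticConfig(seed=seed, amplitude=amp)
                _, truth = ip.generate_dimorphic_locus(cfg)
                if truth.dxy_by_bin:
                    b0 = truth.dxy_by_bin[0]
                    first.append(b0[1] / b0[2])
            means.append(np.mean(first))
        assert means[0] <= means[1] <= means[2]

    def test_default_locus_is_called_dimorphic(self):
        from indelpoly import coalescent as co
        null21 = co.build_null_distribution(
            co.NullModelConfig(n=21, theta=4.0, replicates=4000, seed=3))
        called = 0
        n_trials = 40
        for seed in range(n_trials):
            a, _ = ip.generate_dimorphic_locus(ip.SyntheticConfig(seed=seed))
            groups = ip.find_linked_snp_groups(a)
            calls = ip.call_dimorphism(groups, null21, k_min=3, alpha=0.05)
            called += any(c.is_dimorphic for c in calls)
        assert called / n_trials >= 0.95


class TestNeutralGenerator:
    def test_theta_zero_monomorphic(self):
        cfg = ip.SyntheticConfig(seed=2, indel_size=0, theta_locus=0.0)
        a, truth = ip.generate_neutral_locus(cfg)
        assert popgen.segregating_sites(a) == 0

    def test_segregating_sites_match_watterson(self):
        n, theta = 21, 4.0
        S = []
        for seed in range(600):
            cfg = ip.SyntheticConfig(n1=10, n2=11, length=600, indel_size=0,
                                     theta_locus=theta, seed=seed)
            a, _ = ip.generate_neutral_locus(cfg)
            S.append(popgen.segregating_sites(a))
        expect = theta * harmonic_number(n - 1)
        assert np.mean(S) == pytest.approx(expect, rel=0.05)

    def test_bernoulli_path_plants_no_fixed_sites(self):
        cfg = ip.SyntheticConfig(seed=4, indel_size=200)
        a, truth = ip.generate_neutral_locus(cfg)
        assert truth.fixed_sites == ()


class TestCompoundGenerator:
    def test_disjoint_assignment_recovered(self):
        cfg = ip.SyntheticConfig(seed=8, length=4000, junction=1000,
                                 indel_size=200, max_plant_distance=800,
                                 homogenization_p=0.0)
        a, truth = ip.generate_compound_locus(cfg, 3000, 150)
        groups = ip.find_linked_snp_groups(a)
        events = aio.extract_indels(a, min_size=100)
        m = ip.link_snps_to_indels(groups, events, a.sample_ids, max_dist=1000)
        got = {}
        for g, ev, _ in m.assignments:
            got.setdefault(ev.span, set()).update(g.columns)
        assert got.get(truth.indel_span, set()) == set(truth.fixed_columns())
        assert got.get(truth.second_indel_span, set()) == \
            set(c for c, _ in truth.second_fixed_sites)

    def test_second_indel_without_divergence(self):
        cfg = ip.SyntheticConfig(seed=9, length=4000, junction=1000,
                                 indel_size=200, amplitude=0.0)
        a, truth = ip.generate_compound_locus(cfg, 3000, 150, verify=False)
        assert truth.fixed_sites == () and truth.second_fixed_sites == ()
        assert len(aio.extract_indels(a, min_size=100)) == 2

    def test_nested_partition_stays_unique(self):
        cfg = ip.SyntheticConfig(seed=10, length=4000, junction=1000,
                                 indel_size=200, max_plant_distance=800,
                                 homogenization_p=0.0)
        # second indel carried by a subset of the x haplogroup
        a, truth = ip.generate_compound_locus(cfg, 3000, 150,
                                              second_carriers=range(4))
        groups = ip.find_linked_snp_groups(a)
        events = aio.extract_indels(a, min_size=100)
        m = ip.link_snps_to_indels(groups, events, a.sample_ids, max_dist=1000)
        got = {}
        for g, ev, _ in m.assignments:
            got.setdefault(ev.span, set()).update(g.columns)
        assert got.get(truth.second_indel_span, set()) == \
            set(c for c, _ in truth.second_fixed_sites)

    def test_overlapping_spans_rejected(self):
        cfg = ip.SyntheticConfig(seed=11, junction=1000, indel_size=500)
        with pytest.raises(ValueError):
            ip.generate_compound_locus(cfg, 1200, 100)


class TestFixtureSets:
    def _hashes(self, d):
        return {p.name: hashlib.md5(p.read_bytes()).hexdigest()
                for p in sorted(Path(d).iterdir())}

    def test_manifest_round_trip_is_byte_identical(self, tmp_path):
        specs = synthetic.table1_like_specs(seed=5)[:6]
        man = ip.write_fixture_set(specs, tmp_path / "one")
        ip.write_fixture_set(synthetic.read_manifest(man), tmp_path / "two")
        assert self._hashes(tmp_path / "one") == self._hashes(tmp_path / "two")

    def test_table1_like_structure(self, tmp_path):
        specs = synthetic.table1_like_specs(seed=1)
        assert len(specs) == 18
        kinds = [s.kind for s in specs]
        assert kinds.count("dimorphic") == 15 and kinds.count("compound") == 3

    def test_empty_spec_list(self, tmp_path):
        man = ip.write_fixture_set([], tmp_path / "empty")
        assert man.read_text() == ""
        assert list((tmp_path / "empty").iterdir()) == [man]


class TestMatchedJunction:
    def test_counts_reproduced_through_pipeline(self):
        a = ip.generate_matched_junction_locus(10, 11, 600, 37, 5, 11, seed=3)
        ev = aio.extract_indels(a, min_size=1)[0]
        p = dimorphism.partition_by_indel(a, ev)
        dec = ip.decompose_diversity(a, p)
        assert dec.S_N == 37
        assert dec.fixed_indel_count == 5
        assert dec.effective_length == 589
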