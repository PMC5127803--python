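import numpy as np
import pytest

import indelpoly as ip
from indelpoly import alignment_io as aio
from indelpoly import dimorphism as dm

from .conftest import random_alignment
from . import oracles


def make(seqs, ids=None, locus="L"):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return ip.Alignment.from_sequences(locus, ids, seqs)


def event(presence, start=10, end=20, kind=None):
    return aio.IndelEvent("L", start, end, tuple(presence), kind)


class TestPartitionByIndel:
    def base(self, presence):
        seqs = []
        for p in presence:
            seqs.append(("A" * 10 + ("-" if p == "A" else "C") * 10 + "A" * 10)
                        if p != "U" else "A" * 10 + "N" * 10 + "A" * 10)
        return make(seqs)

    def test_minor_side_is_x(self):
        a = self.base("PPAAA")
        (ev,) = ip.extract_indels(a)
        part = ip.partition_by_indel(a, ev)
        assert part.x_members == ("s0", "s1") and part.n2 == 3

    def test_unknown_samples_dropped(self):
        a = self.base("PAUAA")
        ev = [e for e in ip.extract_indels(a) if e.size == 10][0]
        part = ip.partition_by_indel(a, ev)
        assert part.n1 == 1 and part.n2 == 3 and part.dropped == 1

    def test_tie_goes_to_insertion_carriers(self):
        a = self.base("PPAA")
        ev = event("PPAA", kind="insertion")
        part = dm.partition_by_indel(a, ev)
        assert part.x_members == ("s0", "s1")

    def test_tie_without_kind_uses_smallest_id(self):
        a = self.base("APPA")
        ev = event("APPA")
        part = dm.partition_by_indel(a, ev)
        assert "s0" in part.x_members

    def test_monomorphic_indel_rejected(self):
        a = self.base("PPPP")
        with pytest.raises(dm.MonomorphicIndelError):
            dm.partition_by_indel(a, event("PPPP"))


class TestLinkedSnpGroups:
    def test_constructed_groups(self):
        # cols 1 and 3 split {s0,s1}|{s2,s3,s4}; col 5 splits {s0}|rest
        seqs = ["ACACAC", "ACACAA", "AAAAAA", "AAAAAA", "AAAAAA"]
        a = make(seqs)
        groups = ip.find_linked_snp_groups(a)
        assert [g.k for g in groups] == [2, 1]
        assert groups[0].columns == (1, 3)
        assert groups[0].minor_count == 2

    def test_no_snps_is_empty(self):
        assert ip.find_linked_snp_groups(make(["AAAA"] * 4)) == []

    def test_triallelic_columns_excluded(self):
        a = make(["AAAA", "ACAA", "AGAA", "AAAA"])
        assert ip.find_linked_snp_groups(a) == []

    def test_partition_refinement_and_oracle_equality(self, rng):
        for _ in range(15):
            a = random_alignment(rng, 8, 60, missing=0.05)
            groups = ip.find_linked_snp_groups(a)
            cols = [c for g in groups for c in g.columns]
            assert len(cols) == len(set(cols))  # each SNP in exactly one group
            oracle = oracles.group_snps_by_pattern(a.sequences(), a.sample_ids)
            # same set of column groupings, restricted to retained columns
            retained = set(aio.retained_columns(a).tolist())
            expect = sorted(tuple(c for c in v if c in retained)
                            for v in oracle.values()
                            if any(c in retained for c in v))
            got = sorted(g.columns for g in groups)
            assert got == [e for e in expect if e]


class FakeNull:
    """Stand-in null with a fixed probability lookup (synthetic)."""

    def __init__(self, table):
        self.table = table

    def probability(self, k, minor):
        return self.table.get((k, minor), 1.0)


class TestCallDimorphism:
    def group(self, k, minor):
        sides = (frozenset(f"a{i}" for i in range(minor)),
                 frozenset(f"b{i}" for i in range(minor, minor + 5)))
        return dm.LinkedSnpGroup(sides, tuple(range(k)), minor)

    def test_qualifying_group_called(self):
        null = FakeNull({(3, 10): 0.03})
        (call,) = ip.call_dimorphism([self.group(3, 10)], null, minor_floor=10)
        assert call.is_dimorphic and call.null_probability == 0.03

    def test_k_below_threshold_never_called(self):
        null = FakeNull({(2, 10): 0.0001})
        (call,) = ip.call_dimorphism([self.group(2, 10)], null, minor_floor=10)
        assert not call.is_dimorphic

    def test_minor_floor_enforced(self):
        null = FakeNull({(4, 5): 0.001})
        (call,) = ip.call_dimorphism([self.group(4, 5)], null, minor_floor=10)
        assert not call.is_dimorphic

    def test_missing_null_rejected(self):
        with pytest.raises(ValueError):
            ip.call_dimorphism([self.group(3, 10)], None)


class TestLinkSnpsToIndels:
    def locus(self):
        cfg = ip.SyntheticConfig(seed=23, length=3000, junction=1400,
                                 indel_size=200, max_plant_distance=900,
                                 homogenization_p=0.0)
        return ip.generate_dimorphic_locus(cfg)

    def test_matching_group_assigned_within_distance(self):
        a, truth = self.locus()
        groups = ip.find_linked_snp_groups(a)
        events = aio.extract_indels(a, min_size=100)
        m = ip.link_snps_to_indels(groups, events, a.sample_ids, max_dist=1000)
        assigned_cols = {c for g, ev, _ in m.assignments for c in g.columns
                         if ev.span == truth.indel_span}
        assert assigned_cols == set(truth.fixed_columns())

    def test_distance_rule_unassigns_far_groups(self):
        a, truth = self.locus()
        groups = [g for g in ip.find_linked_snp_groups(a)
                  if set(g.columns) <= set(truth.fixed_columns())]
        events = aio.extract_indels(a, min_size=100)
        m = ip.link_snps_to_indels(groups, events, a.sample_ids, max_dist=10)
        assert not m.assignments and len(m.unassigned_groups) == len(groups)

    def test_relabeling_and_shift_invariance(self):
        a, truth = self.locus()
        groups = ip.find_linked_snp_groups(a)
        events = aio.extract_indels(a, min_size=100)
        m1 = ip.link_snps_to_indels(groups, events, a.sample_ids)
        # shift every column by prepending 7 monomorphic columns
        pad = np.full((a.n, 7), ord("G"), dtype=np.uint8)
        shifted = ip.Alignment(a.locus_id, a.sample_ids,
                               np.concatenate([pad, a.matrix], axis=1))
        g2 = ip.find_linked_snp_groups(shifted)
        e2 = aio.extract_indels(shifted, min_size=100)
        m2 = ip.link_snps_to_indels(g2, e2, shifted.sample_ids)
        pairs1 = sorted((tuple(g.columns), ev.span) for g, ev, _ in m1.assignments)
        pairs2 = sorted((tuple(c - 7 for c in g.columns),
                         (ev.start - 7, ev.end - 7)) for g, ev, _ in m2.assignments)
        assert pairs1 == pairs2


class TestFirstEncounteredVariant:
    def fixture(self):
        # SNP at col 10 and indel at col 40, both differentiating s0/s1
        seqs = []
        for i in range(6):
            row = list("A" * 80)
            if i in (0, 2):
                row[10] = "T"
            if i in (0, 3, 4):
                row[40:50] = "-" * 10
            seqs.append("".join(row))
        return make(seqs)

    def test_indel_mode_picks_gap_event(self):
        part = ip.first_encountered_variant(self.fixture(), "indel", ("s0", "s1"))
        assert isinstance(part.source, aio.IndelEvent)
        assert part.source.start == 40
        assert set(part.x_members) == {"s0", "s3", "s4"}

    def test_snp_mode_picks_leftmost_snp(self):
        part = ip.first_encountered_variant(self.fixture(), "snp", ("s0", "s1"))
        assert part.source == ("snp", 10)
        assert set(part.x_members) == {"s0", "s2"}

    def test_scan_matches_left_to_right_oracle(self, rng):
        a = random_alignment(rng, 6, 100)
        ra, rb = a.sample_ids[0], a.sample_ids[1]
        part = ip.first_encountered_variant(a, "snp", (ra, rb))
        cols = [c for c in aio.retained_columns(a)
                if a.matrix[0, c] != a.matrix[1, c]]
        assert part.source == ("snp", cols[0])

    def test_no_qualifying_variant_rejected(self):
        a = make(["AAAA", "AAAA", "ACAA"])
        with pytest.raises(ValueError):
            ip.first_encountered_variant(a, "indel", ("s0", "s1"))
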