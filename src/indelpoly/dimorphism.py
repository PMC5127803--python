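"""Haplogroup partitioning, linked-SNP grouping and dimorphism calling.

A *dimorphism* is a locus whose haplotypes fall into two distinct sets
separated by several mutually linked SNPs — SNP columns that induce the
identical bipartition of the samples (perfect association).  Following the
empirical criterion calibrated against the neutral coalescent, a locus is
called dimorphic when it carries a group of >= 3 mutually linked SNPs whose
minor-side frequency reaches the floor (10/96 in the reference survey) and
whose probability under the neutral null falls below alpha.

Linked-SNP groups that uniquely match an indel's presence/absence pattern
and lie within 1 kb of the indel are *indel-linked mutations*; loci with
two indels carrying disjoint linked sets show *compound dimorphisms*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import alignment_io as aio
from .alignment_io import Alignment, IndelEvent


class MonomorphicIndelError(ValueError):
    """The indel is not polymorphic in this alignment."""


@dataclass(frozen=True)
class HaplogroupPartition:
    """Minor (x, n1) / major (y, n2) haplogroup split of the samples.

    Samples of unknown genotype at the source variant belong to neither
    side; their count is kept in ``dropped``.
    """

    x_members: tuple
    y_members: tuple
    source: object = None
    dropped: int = 0

    def __post_init__(self) -> None:
        if set(self.x_members) & set(self.y_members):
            raise ValueError("haplogroups must be disjoint")
        if len(self.x_members) < 1 or len(self.y_members) < 1:
            raise ValueError("both haplogroups need at least one member")
        if len(self.x_members) > len(self.y_members):
            raise ValueError("x must be the minor haplogroup (n1 <= n2)")

    @property
    def n1(self) -> int:
        return len(self.x_members)

    @property
    def n2(self) -> int:
        return len(self.y_members)

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @classmethod
    def from_sides(cls, side_a: Sequence[str], side_b: Sequence[str],
                   source=None, dropped: int = 0,
                   prefer_x: Sequence[str] | None = None) -> "HaplogroupPartition":
        """Build a partition with the minor side as x.

        Ties (equal sizes) go to ``prefer_x`` if it matches one side, else
        to the side containing the lexicographically smallest sample id.
        """
        a, b = tuple(side_a), tuple(side_b)
        if len(a) < len(b):
            x, y = a, b
        elif len(b) < len(a):
            x, y = b, a
        else:
            if prefer_x is not None and set(prefer_x) == set(a):
                x, y = a, b
            elif prefer_x is not None and set(prefer_x) == set(b):
                x, y = b, a
            elif min(a) < min(b):
                x, y = a, b
            else:
                x, y = b, a
        return cls(x, y, source=source, dropped=dropped)


def partition_by_indel(alignment: Alignment, event: IndelEvent) -> HaplogroupPartition:
    """Split the accessions by presence/absence of one indel.

    x is the minor side; equal-size ties go to the insertion-carrying group
    when the event kind is known, else to the side with the smallest id.
    Unknown-presence samples are dropped.
    """
    present = event.present_ids(alignment.sample_ids)
    absent = event.absent_ids(alignment.sample_ids)
    unknown = event.unknown_ids(alignment.sample_ids)
    if not present or not absent:
        raise MonomorphicIndelError(
            f"indel at {event.span} is monomorphic ({len(present)} present, {len(absent)} absent)"
        )
    prefer = present if event.kind == "insertion" else None
    return HaplogroupPartition.from_sides(present, absent, source=event,
                                          dropped=len(unknown), prefer_x=prefer)


# ---------------------------------------------------------------------------
# linked-SNP groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkedSnpGroup:
    """A set of SNP columns inducing the identical sample bipartition.

    ``signature`` is the canonical bipartition (the side containing the
    lexicographically smallest called sample id first); ``columns`` are the
    0-based SNP positions sharing it.
    """

    signature: tuple  # (frozenset, frozenset)
    columns: tuple
    minor_count: int

    @property
    def k(self) -> int:
        return len(self.columns)

    @property
    def extension(self) -> tuple:
        """Span from first to last column of the group."""
        return (min(self.columns), max(self.columns))

    @property
    def midpoint(self) -> float:
        lo, hi = self.extension
        return (lo + hi) / 2

    def to_partition(self, source=None) -> HaplogroupPartition:
        a, b = self.signature
        return HaplogroupPartition.from_sides(tuple(sorted(a)), tuple(sorted(b)),
                                              source=source)


def _canonical(side_a: frozenset, side_b: frozenset) -> tuple:
    return (side_a, side_b) if min(side_a) < min(side_b) else (side_b, side_a)


def find_linked_snp_groups(alignment: Alignment) -> list:
    """Group biallelic SNP columns by identical canonical bipartition.

    Columns are grouped only when they share the same called sample set and
    the same split of it (exact-signature grouping); groups are sorted by
    size (k) descending, then by first column.
    """
    mat = alignment.matrix
    called = aio.called_mask(alignment)
    groups: dict = {}
    for col in aio.retained_columns(alignment):
        ok = called[:, col]
        bases = mat[ok, col]
        uniq = np.unique(bases)
        if uniq.size != 2:  # biallelic columns only
            continue
        ids = [s for s, c in zip(alignment.sample_ids, ok) if c]
        side_a = frozenset(s for s, b in zip(ids, bases) if b == uniq[0])
        side_b = frozenset(s for s, b in zip(ids, bases) if b == uniq[1])
        groups.setdefault(_canonical(side_a, side_b), []).append(int(col))
    out = [
        LinkedSnpGroup(sig, tuple(cols), min(len(sig[0]), len(sig[1])))
        for sig, cols in groups.items()
    ]
    out.sort(key=lambda g: (-g.k, g.columns[0]))
    return out


# ---------------------------------------------------------------------------
# dimorphism calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimorphismCall:
    """One linked-SNP group scored against the coalescent null."""

    locus_id: str
    group: LinkedSnpGroup
    null_probability: float
    is_dimorphic: bool

    @property
    def extension(self) -> tuple:
        return self.group.extension


def call_dimorphism(groups: Iterable[LinkedSnpGroup], null, k_min: int = 3,
                    alpha: float = 0.05, minor_floor: int | None = None,
                    locus_id: str = "") -> list:
    """Score linked-SNP groups against a neutral null distribution.

    A group is dimorphic iff k >= ``k_min``, its minor count reaches
    ``minor_floor`` (when given), and its null probability — P(>= k linked
    SNPs at >= its minor count) — falls below ``alpha`` *and* below the
    null's family-wise threshold, which corrects for the many group sizes
    a locus offers so the per-locus false-positive rate stays at ``alpha``
    (see :meth:`indelpoly.coalescent.NullDistribution.family_threshold`).
    ``null`` must provide ``probability(k, minor_floor)``.
    """
    if null is None:
        raise ValueError("a null distribution is required")
    thr = None
    if hasattr(null, "family_threshold"):
        thr = null.family_threshold(alpha=alpha, k_min=k_min,
                                    minor_floor=minor_floor or 1)
    calls = []
    for g in groups:
        p = null.probability(g.k, g.minor_count)
        ok = (
            g.k >= k_min
            and (minor_floor is None or g.minor_count >= minor_floor)
            and p < alpha
            and (thr is None or p <= thr)
        )
        calls.append(DimorphismCall(locus_id, g, p, ok))
    return calls


# ---------------------------------------------------------------------------
# linking SNP groups to indels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundDimorphismMap:
    """Assignment of linked-SNP groups to indels by shared presence pattern.

    ``assignments`` holds (group, event, distance) triples; a group maps to
    at most one indel, ambiguity resolved toward the nearer one.
    """

    assignments: tuple
    unassigned_groups: tuple
    unassigned_indels: tuple

    @property
    def fraction_indels_linked(self) -> float:
        linked = {(ev.start, ev.end) for _, ev, _ in self.assignments}
        total = len(linked) + len(self.unassigned_indels)
        return len(linked) / total if total else 0.0

    @property
    def fraction_snps_linked(self) -> float:
        assigned = sum(g.k for g, _, _ in self.assignments)
        total = assigned + sum(g.k for g in self.unassigned_groups)
        return assigned / total if total else 0.0


def _pattern_matches(group: LinkedSnpGroup, present: frozenset, absent: frozenset) -> bool:
    """Exact bipartition identity on the jointly called/genotyped samples."""
    ga, gb = group.signature
    common = (present | absent) & (ga | gb)
    ca, cb = ga & common, gb & common
    ea, eb = present & common, absent & common
    if not (ca and cb):
        return False
    return {ca, cb} == {ea, eb}


def link_snps_to_indels(groups: Iterable[LinkedSnpGroup],
                        indels: Iterable[IndelEvent],
                        sample_ids: Sequence[str],
                        max_dist: int = 1000) -> CompoundDimorphismMap:
    """Assign linked-SNP groups to indels sharing their presence pattern.

    A group is assigned when its bipartition equals the indel's
    present/absent split (on samples genotyped in both) and every group
    column lies within ``max_dist`` of the indel span; among several
    matching indels the nearest wins.
    """
    indels = list(indels)
    assignments = []
    unassigned_groups = []
    for g in groups:
        matches = []
        for ev in indels:
            present = frozenset(ev.present_ids(sample_ids))
            absent = frozenset(ev.absent_ids(sample_ids))
            if not present or not absent:
                continue
            if not _pattern_matches(g, present, absent):
                continue
            dists = [ev.distance_to_column(c) for c in g.columns]
            if max(dists) <= max_dist:
                matches.append((min(dists), ev.start, ev))
        if matches:
            matches.sort(key=lambda t: (t[0], t[1]))
            dist, _, ev = matches[0]
            assignments.append((g, ev, dist))
        else:
            unassigned_groups.append(g)
    linked_spans = {(ev.start, ev.end) for _, ev, _ in assignments}
    unassigned_indels = tuple(ev for ev in indels if (ev.start, ev.end) not in linked_spans)
    return CompoundDimorphismMap(tuple(assignments), tuple(unassigned_groups),
                                 unassigned_indels)


# ---------------------------------------------------------------------------
# reference-pair scans
# ---------------------------------------------------------------------------

def first_encountered_variant(alignment: Alignment, mode: str,
                              ref_pair: Sequence[str]) -> HaplogroupPartition:
    """Partition all samples by the leftmost variant differentiating a
    named accession pair (e.g. Col-0 vs Ler-1).

    ``mode='indel'`` picks the first gap-run event at which one reference is
    present and the other absent; ``mode='snp'`` picks the first biallelic
    SNP column at which both references are called and differ, assigning
    each sample to the side whose reference base it carries (other bases or
    uncalled samples are dropped).
    """
    ra, rb = ref_pair
    idx = {s: i for i, s in enumerate(alignment.sample_ids)}
    if ra not in idx or rb not in idx:
        raise ValueError("reference samples missing from alignment")
    if mode == "indel":
        for ev in extract_sorted_indels(alignment):
            pa, pb = ev.presence[idx[ra]], ev.presence[idx[rb]]
            if {pa, pb} == {"P", "A"}:
                return partition_by_indel(alignment, ev)
        raise ValueError(f"no indel differentiates {ra!r} and {rb!r}")
    if mode == "snp":
        mat = alignment.matrix
        called = aio.called_mask(alignment)
        for col in aio.retained_columns(alignment):
            if not (called[idx[ra], col] and called[idx[rb], col]):
                continue
            ba, bb = mat[idx[ra], col], mat[idx[rb], col]
            if ba == bb:
                continue
            side_a = [s for s in alignment.sample_ids
                      if called[idx[s], col] and mat[idx[s], col] == ba]
            side_b = [s for s in alignment.sample_ids
                      if called[idx[s], col] and mat[idx[s], col] == bb]
            dropped = alignment.n - len(side_a) - len(side_b)
            return HaplogroupPartition.from_sides(side_a, side_b,
                                                  source=("snp", int(col)),
                                                  dropped=dropped)
        raise ValueError(f"no SNP differentiates {ra!r} and {rb!r}")
    raise ValueError("mode must be 'indel' or 'snp'")


def extract_sorted_indels(alignment: Alignment, min_size: int = 1) -> list:
    """Indel events in left-to-right order of their start column."""
    return sorted(aio.extract_indels(alignment, min_size=min_size),
                  key=lambda e: (e.start, e.end))


def write_dimorphism_report(calls: Iterable[DimorphismCall], mapping, path,
                            header: str = "") -> None:
    """TSV report: locus, group index, k, minor count, extension,
    null probability, dimorphic flag, linked indel span, distance."""
    linked = {}
    if mapping is not None:
        for g, ev, dist in mapping.assignments:
            linked[g.columns] = (ev, dist)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("locus\tgroup\tk\tminor_count\textension_start\textension_end\t"
                 "null_probability\tdimorphic\tlinked_indel\tdistance\n")
        for i, call in enumerate(calls):
            g = call.group
            ev_dist = linked.get(g.columns)
            ev_str = f"{ev_dist[0].start}-{ev_dist[0].end}" if ev_dist else "."
            dist_str = str(ev_dist[1]) if ev_dist else "."
            lo, hi = g.extension
            fh.write(f"{call.locus_id}\t{i}\t{g.k}\t{g.minor_count}\t{lo}\t{hi}\t"
                     f"{call.null_probability:.6g}\t{int(call.is_dimorphic)}\t"
                     f"{ev_str}\t{dist_str}\n")
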