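"""Population-genetic summary statistics and the diversity decomposition.

At a dimorphic locus the accessions split into a minor haplogroup *x*
(n1 members) and a major haplogroup *y* (n2 members, n = n1 + n2).  Nei's
nucleotide diversity of the whole sample then decomposes exactly into a
within-haplogroup term and two between-haplogroup terms::

    pi_t = n1(n1-1)/(n(n-1)) * pi_x  +  n2(n2-1)/(n(n-1)) * pi_y
         + 2 n1 n2 / (n(n-1)) * D_xy
         = pi_h + pi_fixedxy + pi_nonfixedxy

where ``D_xy`` is the mean pairwise between-group divergence per site,
``d_xy`` is the *fixed* divergence (count of sites at which the two
haplogroups carry different, internally fixed bases, divided by the
effective length), ``pi_fixedxy = 2 n1 n2 / (n(n-1)) * d_xy`` and
``pi_nonfixedxy`` carries the remaining (shared/segregating) between-group
differences.

All statistics count differences over the retained columns (>= 90% of
samples called) with pairwise deletion in the numerator, and normalize by
the common effective length.  On complete data this equals per-pair
normalization; with missing data it keeps the decomposition identity exact
to floating-point rounding.  Indel variation fixed within haplogroups must
be masked (:func:`indelpoly.alignment_io.mask_fixed_indels`) before
divergence is computed; masked columns drop out of the effective length,
which is what reconciles a fixed-substitution count with a per-site d_xy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import alignment_io as aio
from .alignment_io import Alignment


# ---------------------------------------------------------------------------
# column-wise difference counting
# ---------------------------------------------------------------------------

def _base_counts(alignment: Alignment, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """(4, len(cols)) counts of A/C/G/T among ``rows``, plus called totals."""
    sub = alignment.matrix[np.ix_(rows, cols)]
    return np.stack([(sub == b).sum(axis=0) for b in aio._BASE_BYTES])


def _within_diff_sum(counts: np.ndarray) -> float:
    """Total pairwise differences across columns for one group.

    Per column with m called samples and base counts c_b the number of
    differing called pairs is C(m,2) - sum_b C(c_b,2).
    """
    m = counts.sum(axis=0)
    pairs = m * (m - 1) // 2 - (counts * (counts - 1) // 2).sum(axis=0)
    return float(pairs.sum())


def _cross_diff_sum(counts1: np.ndarray, counts2: np.ndarray) -> float:
    """Total differing cross-group called pairs: m1*m2 - sum_b c1_b*c2_b."""
    m1 = counts1.sum(axis=0)
    m2 = counts2.sum(axis=0)
    return float((m1 * m2 - (counts1 * counts2).sum(axis=0)).sum())


def _group_rows(alignment: Alignment, members) -> np.ndarray:
    idx = {s: i for i, s in enumerate(alignment.sample_ids)}
    return np.asarray([idx[s] for s in members], dtype=np.intp)


# ---------------------------------------------------------------------------
# single-sample statistics
# ---------------------------------------------------------------------------

def nucleotide_diversity(alignment: Alignment) -> float:
    """Nei's per-site mean pairwise nucleotide diversity (pi).

    Returns NaN when no column is callable.
    """
    n = alignment.n
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two samples")
    cols = aio.retained_columns(alignment)
    if cols.size == 0:
        return math.nan
    counts = _base_counts(alignment, np.arange(n), cols)
    total = _within_diff_sum(counts)
    return total / (n * (n - 1) / 2) / cols.size


def segregating_sites(alignment: Alignment) -> int:
    """Number of retained columns with >= 2 distinct called bases."""
    cols = aio.retained_columns(alignment)
    if cols.size == 0:
        return 0
    counts = _base_counts(alignment, np.arange(alignment.n), cols)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def harmonic_number(m: int) -> float:
    """a_m = sum_{j=1}^{m} 1/j."""
    if m < 0:
        raise ValueError("m must be >= 0")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(S: int, n: int, length: float) -> float:
    """Watterson's per-site estimator theta_W = S / a_{n-1} / length."""
    if n < 2:
        raise ValueError("Watterson's theta needs n >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / harmonic_number(n - 1) / length


def tajimas_d(alignment: Alignment) -> float:
    """Tajima's (1989) D from S and the mean pairwise difference count.

    Returns NaN (undefined) for monomorphic alignments rather than a
    silent 0.  Uses the original variance coefficients, no small-sample
    correction.
    """
    n = alignment.n
    S = segregating_sites(alignment)
    if S == 0:
        return math.nan
    cols = aio.retained_columns(alignment)
    counts = _base_counts(alignment, np.arange(n), cols)
    khat = _within_diff_sum(counts) / (n * (n - 1) / 2)

    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


@dataclass(frozen=True)
class SummaryStats:
    """Per-locus summary: n, S, pi, Watterson's theta, Tajima's D."""

    n: int
    S: int
    pi: float
    theta_w: float
    tajima_d: float
    effective_length: int


def summary_stats(alignment: Alignment) -> SummaryStats:
    leff = aio.effective_length(alignment)
    S = segregating_sites(alignment)
    return SummaryStats(
        n=alignment.n,
        S=S,
        pi=nucleotide_diversity(alignment),
        theta_w=watterson_theta(S, alignment.n, leff) if leff else math.nan,
        tajima_d=tajimas_d(alignment),
        effective_length=leff,
    )


# ---------------------------------------------------------------------------
# between-haplogroup statistics
# ---------------------------------------------------------------------------

def between_group_dxy(alignment: Alignment, partition) -> float:
    """Mean pairwise between-group divergence per site (D_xy)."""
    xr = _group_rows(alignment, partition.x_members)
    yr = _group_rows(alignment, partition.y_members)
    if xr.size == 0 or yr.size == 0:
        raise ValueError("both haplogroups must be non-empty")
    cols = aio.retained_columns(alignment)
    if cols.size == 0:
        return math.nan
    cx = _base_counts(alignment, xr, cols)
    cy = _base_counts(alignment, yr, cols)
    return _cross_diff_sum(cx, cy) / (xr.size * yr.size) / cols.size


def fixed_divergence_dxy(alignment: Alignment, partition):
    """Fixed divergence d_xy and the fixed-site column list.

    A retained column is *fixed* iff all called x-members share one base,
    all called y-members share another, and the bases differ (columns where
    the groups are internally fixed for different members of a third-allele
    trio count as fixed).  The alignment should already have within-
    haplogroup-fixed indels masked.

    Returns ``(d_xy, fixed_columns, effective_length)``.
    """
    xr = _group_rows(alignment, partition.x_members)
    yr = _group_rows(alignment, partition.y_members)
    if xr.size == 0 or yr.size == 0:
        raise ValueError("both haplogroups must be non-empty")
    cols = aio.retained_columns(alignment)
    if cols.size == 0:
        return math.nan, np.empty(0, dtype=np.intp), 0
    cx = _base_counts(alignment, xr, cols)
    cy = _base_counts(alignment, yr, cols)
    mx = cx.sum(axis=0)
    my = cy.sum(axis=0)
    fixed = (
        (mx > 0) & (my > 0)
        & (cx.max(axis=0) == mx)
        & (cy.max(axis=0) == my)
        & (cx.argmax(axis=0) != cy.argmax(axis=0))
    )
    fixed_cols = cols[fixed]
    return fixed_cols.size / cols.size, fixed_cols, int(cols.size)


@dataclass(frozen=True)
class DiversityDecomposition:
    """All terms of the pi_t = pi_h + pi_fixedxy + pi_nonfixedxy identity."""

    locus_id: str
    n: int
    n1: int
    n2: int
    pi_t: float
    pi_x: float
    pi_y: float
    pi_h: float
    pi_fixedxy: float
    pi_nonfixedxy: float
    D_xy: float
    d_xy: float
    S_N: int
    fixed_indel_count: int
    effective_length: int
    fixed_columns: tuple
    tajima_d: float

    @property
    def fixed_fraction(self) -> float:
        """pi_fixedxy / pi_t: share of diversity from fixed substitutions."""
        return self.pi_fixedxy / self.pi_t if self.pi_t else 0.0


def fixed_diversity_component(d_xy: float, n1: int, n2: int) -> float:
    """pi_fixedxy = 2 n1 n2 / (n(n-1)) * d_xy."""
    n = n1 + n2
    return 2 * n1 * n2 / (n * (n - 1)) * d_xy


def decompose_diversity(alignment: Alignment, partition, mask: bool = True) -> DiversityDecomposition:
    """Full diversity decomposition for one locus and haplogroup partition.

    By default the alignment is first passed through
    :func:`~indelpoly.alignment_io.mask_fixed_indels`; pass ``mask=False``
    if that was already done.
    """
    if len(partition.x_members) == 0 or len(partition.y_members) == 0:
        raise ValueError("degenerate partition: empty haplogroup")
    if mask:
        alignment = aio.mask_fixed_indels(alignment, partition)
    xr = _group_rows(alignment, partition.x_members)
    yr = _group_rows(alignment, partition.y_members)
    n1, n2 = xr.size, yr.size
    n = n1 + n2
    cols = aio.retained_columns(alignment)
    leff = int(cols.size)
    if leff == 0:
        raise ValueError("no callable columns")
    cx = _base_counts(alignment, xr, cols)
    cy = _base_counts(alignment, yr, cols)
    tx = _within_diff_sum(cx)
    ty = _within_diff_sum(cy)
    txy = _cross_diff_sum(cx, cy)

    pi_x = tx / (n1 * (n1 - 1) / 2) / leff if n1 > 1 else 0.0
    pi_y = ty / (n2 * (n2 - 1) / 2) / leff if n2 > 1 else 0.0
    D_xy = txy / (n1 * n2) / leff
    d_xy, fixed_cols, _ = fixed_divergence_dxy(alignment, partition)

    wx = n1 * (n1 - 1) / (n * (n - 1))
    wy = n2 * (n2 - 1) / (n * (n - 1))
    pi_h = wx * pi_x + wy * pi_y
    pi_fixed = fixed_diversity_component(d_xy, n1, n2)
    pi_nonfixed = 2 * n1 * n2 / (n * (n - 1)) * (D_xy - d_xy)
    pi_t = pi_h + pi_fixed + pi_nonfixed

    return DiversityDecomposition(
        locus_id=alignment.locus_id,
        n=n, n1=n1, n2=n2,
        pi_t=pi_t, pi_x=pi_x, pi_y=pi_y, pi_h=pi_h,
        pi_fixedxy=pi_fixed, pi_nonfixedxy=pi_nonfixed,
        D_xy=D_xy, d_xy=d_xy,
        S_N=int(fixed_cols.size),
        fixed_indel_count=alignment.fixed_indel_count,
        effective_length=leff,
        fixed_columns=tuple(int(c) for c in fixed_cols),
        tajima_d=tajimas_d(alignment),
    )


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlidingWindowTrack:
    """Per-window pi and d_xy; positions relative to the deletion junction.

    Windows without callable columns carry NaN, never 0.  ``single_window``
    flags the degenerate case of a window wider than the locus.
    """

    window: int
    step: int
    centers: np.ndarray
    pi_values: np.ndarray
    dxy_values: np.ndarray
    counts: np.ndarray
    single_window: bool = False


def sliding_window_track(alignment: Alignment, partition, window: int = 100,
                         step: int = 25, junction=None, mask: bool = True) -> SlidingWindowTrack:
    """Sliding-window pi and fixed-divergence track.

    ``junction`` may be an :class:`~indelpoly.alignment_io.IndelEvent`; its
    span columns are excluded and window centers are reported relative to
    the junction (negative upstream, positive downstream, indel at 0).
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if mask:
        alignment = aio.mask_fixed_indels(alignment, partition)
    xr = _group_rows(alignment, partition.x_members)
    yr = _group_rows(alignment, partition.y_members)
    n = alignment.n

    all_cols = np.arange(alignment.length)
    if junction is not None:
        all_cols = all_cols[(all_cols < junction.start) | (all_cols >= junction.end)]
    retained = set(aio.retained_columns(alignment).tolist())
    _, fixed_cols, _ = fixed_divergence_dxy(alignment, partition)
    fixed = set(fixed_cols.tolist())

    single = window > all_cols.size
    if single:
        starts = [0]
        window = all_cols.size
    else:
        starts = list(range(0, all_cols.size - window + 1, step))

    centers, pis, dxys, cnts = [], [], [], []
    allr = np.arange(n)
    for s in starts:
        wcols = all_cols[s:s + window]
        rcols = np.asarray([c for c in wcols if c in retained], dtype=np.intp)
        mid = int(wcols[len(wcols) // 2])
        if junction is not None:
            rel = mid - junction.start if mid < junction.start else mid - junction.end + 1
        else:
            rel = mid
        centers.append(rel)
        if rcols.size == 0:
            pis.append(math.nan)
            dxys.append(math.nan)
            cnts.append(0)
            continue
        counts = _base_counts(alignment, allr, rcols)
        pis.append(_within_diff_sum(counts) / (n * (n - 1) / 2) / rcols.size)
        dxys.append(sum(1 for c in rcols if int(c) in fixed) / rcols.size)
        cnts.append(int(rcols.size))
    return SlidingWindowTrack(
        window=window, step=step,
        centers=np.asarray(centers),
        pi_values=np.asarray(pis),
        dxy_values=np.asarray(dxys),
        counts=np.asarray(cnts),
        single_window=single,
    )


def write_window_track(track: SlidingWindowTrack, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("center\tpi\td_xy\tn_callable\n")
        for c, p, d, k in zip(track.centers, track.pi_values, track.dxy_values, track.counts):
            fh.write(f"{c}\t{p:.6g}\t{d:.6g}\t{k}\n")
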