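"""Distance profiles of fixed divergence around indels and their decay fit.

Fixed between-haplogroup substitutions cluster at the deletion junction and
thin out with distance; binning d_xy by distance-to-junction across loci
and fitting a one-phase exponential

    y(x) = (y0 - plateau) * exp(-K * x) + plateau,   K >= 0

summarizes how fast the dimorphic signal decays (half-distance ln2/K).
Distances are measured in callable (post-mask) columns, consistent with the
per-site normalization of d_xy; the same machinery re-anchored on a control
SNP (the SNP closest to the midpoint of a dimorphism's extension) gives the
auto-correlation baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import alignment_io as aio
from . import popgen
from .alignment_io import Alignment, IndelEvent


@dataclass(frozen=True)
class LocusDivergence:
    """Per-locus input to a distance profile: the distance (in callable
    columns) of every callable column and of every fixed substitution from
    the anchor (indel span or control SNP)."""

    locus_id: str
    callable_distances: np.ndarray
    fixed_distances: np.ndarray

    @property
    def s_n(self) -> int:
        return int(self.fixed_distances.size)


def _distances(callable_cols: np.ndarray, span: tuple) -> np.ndarray:
    """Distance of each callable column to the span, counted in callable
    columns (adjacent callable column = 0); span columns get -1."""
    start, end = span
    n_left = int(np.searchsorted(callable_cols, start))
    first_right = int(np.searchsorted(callable_cols, end))
    idx = np.arange(callable_cols.size)
    out = np.full(callable_cols.size, -1, dtype=np.int64)
    left = idx < n_left
    out[left] = n_left - 1 - idx[left]
    right = idx >= first_right
    out[right] = idx[right] - first_right
    return out


def locus_divergence(alignment: Alignment, partition, anchor,
                     mask: bool = True) -> LocusDivergence:
    """Compute fixed-site and callable-column distances around an anchor.

    ``anchor`` is an :class:`~indelpoly.alignment_io.IndelEvent` (distance 0
    at the junction) or an integer column (a control SNP; that column is
    excluded from its own profile).
    """
    if mask:
        alignment = aio.mask_fixed_indels(alignment, partition)
    span = anchor.span if isinstance(anchor, IndelEvent) else (int(anchor), int(anchor) + 1)
    cols = aio.retained_columns(alignment)
    keep = (cols < span[0]) | (cols >= span[1])
    cols = cols[keep]
    dists = _distances(cols, span)
    _, fixed_cols, _ = popgen.fixed_divergence_dxy(alignment, partition)
    fixed_set = set(int(c) for c in fixed_cols) - set(range(span[0], span[1]))
    fixed_mask = np.asarray([int(c) in fixed_set for c in cols], dtype=bool)
    return LocusDivergence(alignment.locus_id, dists, dists[fixed_mask])


@dataclass(frozen=True)
class DecayProfile:
    """Binned mean d_xy vs distance from the anchor, across loci.

    ``mean_dxy`` is the across-locus mean of per-locus (fixed / callable)
    per bin; bins without data are NaN; ``sem`` is defined only where at
    least two loci contribute.
    """

    bin_width: int
    bin_edges: np.ndarray
    mean_dxy: np.ndarray
    sem: np.ndarray
    n_loci: np.ndarray
    fixed_totals: np.ndarray
    per_locus: np.ndarray  # (n_loci, n_bins) with NaN for empty bins

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def distance_profile(loci, bin_width: int = 100, max_dist: int = 2000) -> DecayProfile:
    """Aggregate :class:`LocusDivergence` records into a binned profile.

    Every fixed substitution contributes to the bin of its distance; each
    locus contributes fixed/callable per bin and bins are averaged across
    loci (distance 0 at the junction).
    """
    loci = list(loci)
    if not loci:
        raise ValueError("need at least one locus")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = edges.size - 1
    per_locus = np.full((len(loci), n_bins), np.nan)
    fixed_totals = np.zeros(n_bins, dtype=np.int64)
    for i, loc in enumerate(loci):
        cal = loc.callable_distances[loc.callable_distances >= 0]
        cal_counts, _ = np.histogram(cal, bins=edges)
        fix_counts, _ = np.histogram(loc.fixed_distances, bins=edges)
        fixed_totals += fix_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = fix_counts / cal_counts
        per_locus[i] = np.where(cal_counts > 0, vals, np.nan)
    counts = np.sum(~np.isnan(per_locus), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_locus, axis=0)
        std = np.nanstd(per_locus, axis=0, ddof=1)
    sem = np.where(counts >= 2, std / np.sqrt(np.maximum(counts, 1)), np.nan)
    return DecayProfile(bin_width, edges, mean, sem, counts, fixed_totals, per_locus)


# ---------------------------------------------------------------------------
# one-phase exponential decay fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpDecayFit:
    """Fitted y(x) = (y0 - plateau) exp(-K x) + plateau with K >= 0.

    ``r_squared`` is 1 - SS_res/SS_tot against the bin means; when the
    profile is constant (SS_tot = 0) it is reported as 0 with
    ``degenerate`` set.  ``ci`` optionally holds residual-bootstrap 95%
    intervals per parameter.
    """

    y0: float
    plateau: float
    K: float
    r_squared: float
    converged: bool
    degenerate: bool = False
    ci: dict | None = None

    @property
    def half_distance(self) -> float:
        """ln 2 / K: distance at which the excess over the plateau halves."""
        return math.log(2) / self.K if self.K > 0 else math.inf

    def predict(self, x) -> np.ndarray:
        return _model(np.asarray((self.y0, self.plateau, self.K)), np.asarray(x))


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    y0, plateau, K = params
    return (y0 - plateau) * np.exp(-K * x) + plateau


def _fit(x: np.ndarray, y: np.ndarray, p0: np.ndarray):
    return least_squares(
        lambda p: _model(p, x) - y, p0,
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-10, ftol=1e-12, gtol=1e-12, max_nfev=10000,
    )


def fit_one_phase_decay(profile: DecayProfile, bootstrap: int = 0,
                        seed: int | None = None) -> ExpDecayFit:
    """Nonlinear least squares of the one-phase decay over non-missing bins.

    Initialized at y0 = first-bin mean, plateau = last-bin mean,
    K = 1/500 bp; requires >= 4 non-missing bins.  Non-convergence is
    reported (``converged=False`` with the last iterate), never silent.
    When ``bootstrap`` > 0, residual-bootstrap 95% CIs are attached
    (seeded).
    """
    ok = ~np.isnan(profile.mean_dxy)
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-missing bins to fit")
    x = profile.centers[ok]
    y = profile.mean_dxy[ok]
    p0 = np.asarray([y[0], y[-1], 1.0 / 500.0])
    res = _fit(x, y, p0)
    yhat = _model(res.x, x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    degenerate = ss_tot < 1e-30
    r2 = 0.0 if degenerate else 1.0 - ss_res / ss_tot
    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples = np.empty((bootstrap, 3))
        resid = y - yhat
        for b in range(bootstrap):
            yb = yhat + rng.choice(resid, size=resid.size, replace=True)
            samples[b] = _fit(x, yb, res.x).x
        lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
        ci = {name: (float(lo[i]), float(hi[i]))
              for i, name in enumerate(("y0", "plateau", "K"))}
    return ExpDecayFit(float(res.x[0]), float(res.x[1]), float(res.x[2]),
                       r2, bool(res.success), degenerate, ci)


# ---------------------------------------------------------------------------
# control-SNP profiles
# ---------------------------------------------------------------------------

def control_anchor(group) -> int:
    """The SNP column closest to the midpoint of the dimorphism's extension
    (ties toward the smaller column)."""
    mid = group.midpoint
    return min(group.columns, key=lambda c: (abs(c - mid), c))


def control_snp_profile(items, bin_width: int = 100, max_dist: int = 2000) -> DecayProfile:
    """Rebuild the d_xy profile around control SNPs.

    ``items`` yields (alignment, linked-SNP group) pairs; each locus is
    anchored on the group column nearest the midpoint of the group's
    extension and the group's own bipartition defines the haplogroups.
    Loci whose group has no SNP columns are skipped with a warning.
    """
    loci = []
    for alignment, group in items:
        if not group.columns:
            warnings.warn(f"{alignment.locus_id}: no SNPs in group, skipped")
            continue
        anchor = control_anchor(group)
        partition = group.to_partition(source=("snp", anchor))
        loci.append(locus_divergence(alignment, partition, anchor))
    if not loci:
        raise ValueError("no usable loci for the control profile")
    return distance_profile(loci, bin_width=bin_width, max_dist=max_dist)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_profile(profile: DecayProfile, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("bin_start\tbin_end\tmean_dxy\tsem\tn_loci\n")
        for i in range(profile.mean_dxy.size):
            fh.write(f"{profile.bin_edges[i]}\t{profile.bin_edges[i+1]}\t"
                     f"{profile.mean_dxy[i]:.6g}\t{profile.sem[i]:.6g}\t"
                     f"{profile.n_loci[i]}\n")


def write_fit(fit: ExpDecayFit, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("y0\tplateau\tK\thalf_distance\tr_squared\tconverged\n")
        fh.write(f"{fit.y0:.6g}\t{fit.plateau:.6g}\t{fit.K:.6g}\t"
                 f"{fit.half_distance:.6g}\t{fit.r_squared:.6g}\t{int(fit.converged)}\n")
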