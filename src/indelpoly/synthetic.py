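"""Synthetic locus generator with exact truth records.

Emulates the statistical structure the analysis assumes: a large indel
splits the accessions into two haplogroups; fixed between-haplogroup
substitutions accumulate near the deletion junction with density
``A * exp(-d / lambda)`` at distance ``d`` (columns) from the junction;
recombination-style homogenization converts a fraction of the fixed
differences beyond a suppression window into shared polymorphism; and
within-haplogroup background mutations provide ordinary diversity.
Divergence is planted directly as fixed differences — the generator targets
the signature the pipeline measures, not a structured-coalescent mechanism
— so the truth record is exact and recovery tests are sharp.  Neutral
control loci can instead be drawn genealogy-exactly from the coalescent
module.

Default parameters mirror the conditions of the reference survey: 21
accessions at 10:11 indel frequency, a 4-kb locus around a >=100-bp indel,
junction amplitude A = 0.08/site with a 300-bp decay scale (peak fixed
divergence and ~1-kb dimorphism extension of the sequenced non-R loci),
and background diversity ~0.005/site (genome-wide Arabidopsis levels).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import alignment_io as aio
from . import coalescent, dimorphism, popgen
from .alignment_io import Alignment, IndelEvent

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters (defaults = the emulated study conditions)."""

    n1: int = 10                       # minor haplogroup (deletion carriers)
    n2: int = 11                       # major haplogroup
    length: int = 4000                 # alignment columns
    junction: int = 2000               # indel span start
    indel_size: int = 300              # 0 = no indel
    background_theta_site: float = 0.005   # within-group per-site mutation intensity
    amplitude: float = 0.08            # A: fixed-divergence density at the junction
    decay_scale: float = 300.0         # lambda (bp)
    suppression_window: int = 1000     # w: no homogenization within w of the junction
    homogenization_p: float = 0.5      # P(fixed difference beyond w -> shared polymorphism)
    max_plant_distance: int | None = None  # cap on planted fixed-site distance
    theta_locus: float | None = None   # use the coalescent genealogy instead (neutral loci)
    seed: int = 0
    locus_id: str = "synthetic"

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.length) < 1 or self.n1 + self.n2 < 4:
            raise ValueError("need n1, n2 >= 1 and n1 + n2 >= 4")
        if self.indel_size and not (0 <= self.junction and
                                    self.junction + self.indel_size <= self.length):
            raise ValueError("indel span must fit inside the locus")
        for name in ("background_theta_site", "amplitude", "decay_scale",
                     "suppression_window", "homogenization_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def sample_ids(self) -> tuple:
        return tuple(f"x{i+1:02d}" for i in range(self.n1)) + \
               tuple(f"y{i+1:02d}" for i in range(self.n2))


@dataclass(frozen=True)
class TruthRecord:
    """Exact record of everything the generator planted."""

    locus_id: str
    config: SyntheticConfig
    indel_span: tuple | None
    presence: tuple | None
    fixed_sites: tuple          # (column, distance) of surviving fixed substitutions
    homogenized: tuple          # columns converted to shared polymorphism
    within_group: tuple         # (column, group) background mutations
    second_indel_span: tuple | None = None
    second_presence: tuple | None = None
    second_fixed_sites: tuple = ()
    dxy_by_bin: tuple = ()      # (bin_start, fixed, callable) at 100-bp bins

    def fixed_columns(self) -> tuple:
        return tuple(c for c, _ in self.fixed_sites)


class TruthMismatchError(AssertionError):
    """The emitted alignment disagrees with its truth record."""


def _plant_columns(cfg: SyntheticConfig, span: tuple, rng: np.random.Generator,
                   avail: np.ndarray) -> list:
    """Columns (with distances) hit by the junction-centred Poisson
    intensity A*exp(-d/lambda), nearest first."""
    start, end = span
    cols, dists = [], []
    for side_cols in (np.arange(start - 1, -1, -1), np.arange(end, cfg.length)):
        if side_cols.size == 0:
            continue
        d = np.arange(side_cols.size)
        p = np.minimum(cfg.amplitude * np.exp(-d / cfg.decay_scale), 1.0)
        if cfg.max_plant_distance is not None:
            p[d >= cfg.max_plant_distance] = 0.0
        hit = (rng.random(side_cols.size) < p) & avail[side_cols]
        cols.extend(int(c) for c in side_cols[hit])
        dists.extend(int(x) for x in d[hit])
    order = np.argsort(cols)
    return [(cols[i], dists[i]) for i in order]


def _random_nonfixed_pattern(rng: np.random.Generator, n: int,
                             forbidden: Sequence[frozenset]) -> np.ndarray:
    """Random sample subset (1..n-1 members) avoiding the forbidden sets."""
    while True:
        k = int(rng.integers(1, n))
        carriers = rng.choice(n, size=k, replace=False)
        if frozenset(int(c) for c in carriers) not in forbidden:
            return carriers


def _dxy_bins(length: int, span: tuple, fixed_cols: Sequence[int],
              bin_width: int = 100) -> tuple:
    start, end = span
    def dist(col):
        return start - 1 - col if col < start else col - end
    all_cols = [c for c in range(length) if c < start or c >= end]
    cal = np.asarray([dist(c) for c in all_cols])
    fix = np.asarray([dist(c) for c in fixed_cols], dtype=np.int64)
    edges = np.arange(0, (int(cal.max()) if cal.size else 0) + bin_width + 1, bin_width)
    cal_counts, _ = np.histogram(cal, bins=edges)
    fix_counts, _ = np.histogram(fix, bins=edges)
    return tuple((int(edges[i]), int(fix_counts[i]), int(cal_counts[i]))
                 for i in range(edges.size - 1))


def generate_dimorphic_locus(config: SyntheticConfig, verify: bool = True):
    """Generate one indel-split locus; returns (Alignment, TruthRecord).

    The truth record is checked against the emitted alignment at
    generation time (the pipeline's fixed-site call must recover exactly
    the planted, non-homogenized set).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n, cfg.length
    anc = _BASES[rng.integers(0, 4, size=L)]
    mat = np.tile(anc, (n, 1))
    x_rows = np.arange(cfg.n1)
    y_rows = np.arange(cfg.n1, n)
    x_set = frozenset(int(i) for i in x_rows)
    y_set = frozenset(int(i) for i in y_rows)

    avail = np.ones(L, dtype=bool)
    span = None
    if cfg.indel_size:
        span = (cfg.junction, cfg.junction + cfg.indel_size)
        avail[span[0]:span[1]] = False

    fixed_sites, homogenized = [], []
    if span is not None and cfg.amplitude > 0:
        for col, d in _plant_columns(cfg, span, rng, avail):
            new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
            if d > cfg.suppression_window and rng.random() < cfg.homogenization_p:
                carriers = _random_nonfixed_pattern(rng, n, (x_set, y_set))
                mat[carriers, col] = new
                homogenized.append(col)
            else:
                mat[x_rows, col] = new
                fixed_sites.append((col, d))
            avail[col] = False

    within = []
    if cfg.background_theta_site > 0:
        for gname, rows in (("x", x_rows), ("y", y_rows)):
            if rows.size < 2:
                continue
            hits = np.flatnonzero((rng.random(L) < cfg.background_theta_site) & avail)
            for col in hits:
                new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
                k = int(rng.integers(1, rows.size))
                carriers = rng.choice(rows, size=k, replace=False)
                mat[carriers, col] = new
                avail[col] = False
                within.append((int(col), gname))

    presence = None
    if span is not None:
        mat[x_rows, span[0]:span[1]] = aio.GAP
        presence = tuple(["A"] * cfg.n1 + ["P"] * cfg.n2)

    alignment = Alignment(cfg.locus_id, cfg.sample_ids(), mat)
    truth = TruthRecord(
        locus_id=cfg.locus_id, config=cfg,
        indel_span=span, presence=presence,
        fixed_sites=tuple(fixed_sites),
        homogenized=tuple(homogenized),
        within_group=tuple(within),
        dxy_by_bin=_dxy_bins(L, span, [c for c, _ in fixed_sites]) if span else (),
    )
    if verify and span is not None:
        _verify_truth(alignment, truth)
    return alignment, truth


def _verify_truth(alignment: Alignment, truth: TruthRecord) -> None:
    events = aio.extract_indels(alignment, min_size=1)
    ev = next(e for e in events if e.span == truth.indel_span)
    part = dimorphism.partition_by_indel(alignment, ev)
    masked = aio.mask_fixed_indels(alignment, part)
    _, fixed_cols, _ = popgen.fixed_divergence_dxy(masked, part)
    if set(int(c) for c in fixed_cols) != set(truth.fixed_columns()) | set(
            c for c, _ in truth.second_fixed_sites):
        raise TruthMismatchError(
            f"{alignment.locus_id}: recovered fixed sites disagree with truth record")


def generate_neutral_locus(config: SyntheticConfig, verify: bool = False):
    """Neutral control locus: no junction-linked divergence.

    With ``config.theta_locus`` set, the alignment is drawn from the
    neutral coalescent (constant size, panmixia, no recombination,
    infinite sites) with that per-locus theta: each mutation gets a unique
    uniformly-placed column and is carried by its genealogical descendant
    set.  Otherwise this is the Bernoulli background generator with
    amplitude forced to 0.
    """
    cfg = config
    if cfg.theta_locus is None:
        return generate_dimorphic_locus(
            dataclasses.replace(cfg, amplitude=0.0, suppression_window=0), verify=verify)
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n, cfg.length
    anc = _BASES[rng.integers(0, 4, size=L)]
    mat = np.tile(anc, (n, 1))
    masks = coalescent._simulate_masks(n, cfg.theta_locus, rng)
    if len(masks) > L:
        raise ValueError("more mutations than columns; increase length")
    cols = rng.choice(L, size=len(masks), replace=False)
    planted = []
    for mask, col in zip(masks, cols):
        new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
        carriers = [i for i in range(n) if (mask >> i) & 1]
        mat[carriers, col] = new
        planted.append((int(col), "coalescent"))
    alignment = Alignment(cfg.locus_id, cfg.sample_ids(), mat)
    truth = TruthRecord(cfg.locus_id, cfg, None, None, (), (), tuple(planted))
    return alignment, truth


def generate_compound_locus(config: SyntheticConfig, second_junction: int,
                            second_size: int, second_carriers: Sequence[int] | None = None,
                            verify: bool = True):
    """Locus with two indels, each with its own linked fixed-site set.

    The second indel's deletion carriers default to a random subset whose
    pattern differs from the first indel's bipartition (pass explicit row
    indices for nested-partition cases).  Spans must be disjoint.
    """
    cfg = config
    if not cfg.indel_size:
        raise ValueError("compound locus needs a first indel")
    span1 = (cfg.junction, cfg.junction + cfg.indel_size)
    span2 = (second_junction, second_junction + second_size)
    if second_size < 1 or not (0 <= span2[0] < span2[1] <= cfg.length):
        raise ValueError("second indel span must fit inside the locus")
    if not (span2[1] <= span1[0] or span2[0] >= span1[1]):
        raise ValueError("indel spans must be disjoint")

    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n, cfg.length
    anc = _BASES[rng.integers(0, 4, size=L)]
    mat = np.tile(anc, (n, 1))
    x_rows = np.arange(cfg.n1)
    x_set = frozenset(int(i) for i in x_rows)
    y_set = frozenset(range(cfg.n1, n))

    avail = np.ones(L, dtype=bool)
    avail[span1[0]:span1[1]] = False
    avail[span2[0]:span2[1]] = False

    if second_carriers is None:
        while True:
            k = int(rng.integers(2, n - 1))
            carriers2 = np.sort(rng.choice(n, size=k, replace=False))
            cset = frozenset(int(i) for i in carriers2)
            if cset not in (x_set, y_set):
                break
    else:
        carriers2 = np.sort(np.asarray(list(second_carriers), dtype=np.intp))
        cset = frozenset(int(i) for i in carriers2)
        if cset in (x_set, y_set):
            raise ValueError("second indel must define a distinct pattern")

    fixed1, fixed2, homogenized = [], [], []
    for span, carriers, sink in ((span1, x_rows, fixed1), (span2, carriers2, fixed2)):
        forbidden = (x_set, y_set, cset, frozenset(range(n)) - cset)
        for col, d in _plant_columns(cfg, span, rng, avail):
            new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
            if d > cfg.suppression_window and rng.random() < cfg.homogenization_p:
                mat[_random_nonfixed_pattern(rng, n, forbidden), col] = new
                homogenized.append(col)
            else:
                mat[carriers, col] = new
                sink.append((col, d))
            avail[col] = False

    within = []
    if cfg.background_theta_site > 0:
        rows_y = np.arange(cfg.n1, n)
        for gname, rows in (("x", x_rows), ("y", rows_y)):
            if rows.size < 2:
                continue
            hits = np.flatnonzero((rng.random(L) < cfg.background_theta_site) & avail)
            for col in hits:
                new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
                carriers = rng.choice(rows, size=int(rng.integers(1, rows.size)), replace=False)
                mat[carriers, col] = new
                avail[col] = False
                within.append((int(col), gname))

    mat[x_rows, span1[0]:span1[1]] = aio.GAP
    mat[carriers2, span2[0]:span2[1]] = aio.GAP
    presence1 = tuple(["A"] * cfg.n1 + ["P"] * cfg.n2)
    presence2 = tuple("A" if i in cset else "P" for i in range(n))

    alignment = Alignment(cfg.locus_id, cfg.sample_ids(), mat)
    truth = TruthRecord(
        locus_id=cfg.locus_id, config=cfg,
        indel_span=span1, presence=presence1,
        fixed_sites=tuple(fixed1), homogenized=tuple(homogenized),
        within_group=tuple(within),
        second_indel_span=span2, second_presence=presence2,
        second_fixed_sites=tuple(fixed2),
        dxy_by_bin=_dxy_bins(L, span1, [c for c, _ in fixed1]),
    )
    if verify:
        _verify_compound(alignment, truth)
    return alignment, truth


def _verify_compound(alignment: Alignment, truth: TruthRecord) -> None:
    groups = dimorphism.find_linked_snp_groups(alignment)
    planted = {truth.indel_span: set(truth.fixed_columns()),
               truth.second_indel_span: set(c for c, _ in truth.second_fixed_sites)}
    events = {e.span: e for e in aio.extract_indels(alignment, min_size=1)}
    for span, cols in planted.items():
        if not cols:
            continue
        covered = set()
        for g in groups:
            if set(g.columns) <= cols:
                covered |= set(g.columns)
        if covered != cols:
            raise TruthMismatchError(f"{alignment.locus_id}: planted set for {span} "
                                     "not recovered as linked groups")
        if span not in events:
            raise TruthMismatchError(f"{alignment.locus_id}: planted indel {span} not detected")


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """One locus in a fixture set; regeneration is seed-deterministic."""

    kind: str  # dimorphic | neutral | compound
    config: SyntheticConfig
    second_junction: int | None = None
    second_size: int | None = None

    def generate(self):
        if self.kind == "dimorphic":
            return generate_dimorphic_locus(self.config)
        if self.kind == "neutral":
            return generate_neutral_locus(self.config)
        if self.kind == "compound":
            return generate_compound_locus(self.config, self.second_junction,
                                           self.second_size)
        raise ValueError(f"unknown fixture kind {self.kind!r}")


_MANIFEST_FIELDS = [f.name for f in dataclasses.fields(SyntheticConfig)]


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        for name in _MANIFEST_FIELDS:
            fh.write(f"# {name}={getattr(truth.config, name)}\n")
        fh.write("column\tkind\tdetail\n")
        if truth.indel_span:
            fh.write(f"{truth.indel_span[0]}\tindel\tend={truth.indel_span[1]};"
                     f"presence={''.join(truth.presence)}\n")
        if truth.second_indel_span:
            fh.write(f"{truth.second_indel_span[0]}\tindel2\tend={truth.second_indel_span[1]};"
                     f"presence={''.join(truth.second_presence)}\n")
        for col, d in truth.fixed_sites:
            fh.write(f"{col}\tfixed\tdistance={d}\n")
        for col, d in truth.second_fixed_sites:
            fh.write(f"{col}\tfixed2\tdistance={d}\n")
        for col in truth.homogenized:
            fh.write(f"{col}\thomogenized\t.\n")
        for col, g in truth.within_group:
            fh.write(f"{col}\twithin\tgroup={g}\n")


def write_fixture_set(specs: Iterable[FixtureSpec], out_dir) -> Path:
    """Write aligned FASTA + truth TSV per locus and a key=value manifest;
    regeneration from the manifest is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.txt"
    with open(manifest, "w") as fh:
        for spec in specs:
            cfg = spec.config
            a, truth = spec.generate()
            aio.write_alignment(a, out / f"{cfg.locus_id}.fasta")
            write_truth(truth, out / f"{cfg.locus_id}.truth.tsv")
            parts = [f"kind={spec.kind}"]
            parts += [f"{name}={getattr(cfg, name)}" for name in _MANIFEST_FIELDS]
            if spec.kind == "compound":
                parts += [f"second_junction={spec.second_junction}",
                          f"second_size={spec.second_size}"]
            fh.write("\t".join(parts) + "\n")
    return manifest


def read_manifest(path) -> list:
    specs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        kv = dict(item.split("=", 1) for item in line.split("\t"))
        kind = kv.pop("kind")
        second_junction = kv.pop("second_junction", None)
        second_size = kv.pop("second_size", None)
        kwargs = {}
        for f in dataclasses.fields(SyntheticConfig):
            raw = kv[f.name]
            if raw == "None":
                kwargs[f.name] = None
            elif f.name in ("locus_id",):
                kwargs[f.name] = raw
            elif f.name in ("background_theta_site", "amplitude", "decay_scale",
                            "homogenization_p", "theta_locus"):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = int(raw)
        specs.append(FixtureSpec(
            kind, SyntheticConfig(**kwargs),
            int(second_junction) if second_junction not in (None, "None") else None,
            int(second_size) if second_size not in (None, "None") else None,
        ))
    return specs


def table1_like_specs(seed: int = 0) -> list:
    """An 18-locus fixture set with the structure of the reference survey:
    3 high-amplitude R-gene-like loci, 12 moderate single-indel loci and
    3 compound two-indel loci."""
    specs = []
    for i in range(3):
        specs.append(FixtureSpec("dimorphic", SyntheticConfig(
            locus_id=f"RGDL{i+1}", seed=seed * 100 + i,
            amplitude=0.10, decay_scale=400.0, indel_size=500)))
    for i in range(12):
        specs.append(FixtureSpec("dimorphic", SyntheticConfig(
            locus_id=f"NRDL{i+1}", seed=seed * 100 + 10 + i,
            n1=4, n2=5, amplitude=0.04, decay_scale=250.0, indel_size=200)))
    for i in range(3):
        specs.append(FixtureSpec(
            "compound",
            SyntheticConfig(locus_id=f"CPDL{i+1}", seed=seed * 100 + 30 + i,
                            amplitude=0.06, decay_scale=200.0, indel_size=200,
                            max_plant_distance=800, homogenization_p=0.0),
            second_junction=3000, second_size=150))
    return specs


# ---------------------------------------------------------------------------
# reconstruction of tabulated junction regions
# ---------------------------------------------------------------------------

def generate_matched_junction_locus(n1: int, n2: int, length: int, s_n: int,
                                    fixed_indel_count: int, fixed_indel_columns: int,
                                    seed: int = 0, background_theta_site: float = 0.005,
                                    locus_id: str = "matched") -> Alignment:
    """Build a junction-region alignment matching tabulated counts exactly:
    ``s_n`` fixed substitutions and ``fixed_indel_count`` haplogroup-fixed
    indel events totalling ``fixed_indel_columns`` columns, plus background
    within-group polymorphism.  Used to reproduce published per-region
    decompositions from their printed fixed-site counts."""
    if fixed_indel_count > 0 and fixed_indel_columns < fixed_indel_count:
        raise ValueError("need at least one column per fixed indel")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    anc = _BASES[rng.integers(0, 4, size=length)]
    mat = np.tile(anc, (n, 1))
    x_rows = np.arange(n1)

    # non-overlapping, non-adjacent indel spans (adjacent runs would merge)
    sizes = []
    if fixed_indel_count:
        base, extra = divmod(fixed_indel_columns, fixed_indel_count)
        sizes = [base + (1 if i < extra else 0) for i in range(fixed_indel_count)]
    spans = []
    occupied = np.zeros(length, dtype=bool)
    for size in sizes:
        for _ in range(10000):
            start = int(rng.integers(0, length - size))
            if not occupied[max(0, start - 1):start + size + 1].any():
                spans.append((start, start + size))
                occupied[start:start + size] = True
                break
        else:
            raise RuntimeError("could not place indel spans")
    avail = ~occupied
    free = np.flatnonzero(avail)
    fixed_cols = rng.choice(free, size=s_n, replace=False)
    for col in fixed_cols:
        new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
        mat[x_rows, col] = new
        avail[col] = False
    if background_theta_site > 0:
        for rows in (x_rows, np.arange(n1, n)):
            if rows.size < 2:
                continue
            hits = np.flatnonzero((rng.random(length) < background_theta_site) & avail)
            for col in hits:
                new = _BASES[(int(np.searchsorted(_BASES, anc[col])) + int(rng.integers(1, 4))) % 4]
                mat[rng.choice(rows, size=int(rng.integers(1, rows.size)), replace=False),
                    col] = new
                avail[col] = False
    for start, end in spans:
        mat[x_rows, start:end] = aio.GAP
    return Alignment(locus_id, tuple(f"x{i+1:02d}" for i in range(n1)) +
                     tuple(f"y{i+1:02d}" for i in range(n2)), mat)
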