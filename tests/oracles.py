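"""Independent brute-force oracles, written before and apart from the
package implementations they check."""

import itertools
import math
import re

BASES = set("ACGT")


def hamming_pi(seqs):
    """All-pairs per-site diversity on complete (ACGT-only) sequences."""
    n = len(seqs)
    L = len(seqs[0])
    total = sum(
        sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / L


def cross_pair_dxy(x_seqs, y_seqs):
    """Mean cross-pair per-site divergence on complete sequences."""
    L = len(x_seqs[0])
    total = sum(
        sum(a != b for a, b in zip(sx, sy)) for sx in x_seqs for sy in y_seqs
    )
    return total / (len(x_seqs) * len(y_seqs)) / L


def textbook_tajimas_d(seqs):
    """Tajima (1989) statistic, written directly from the defining
    formulas (complete sequences)."""
    n = len(seqs)
    cols = list(zip(*seqs))
    S = sum(1 for col in cols if len(set(col)) > 1)
    if S == 0:
        return math.nan
    k = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        k += sum(a != b for a, b in zip(seqs[i], seqs[j]))
        npairs += 1
    k /= npairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def scan_gap_runs(seq):
    """Maximal '-' runs of one sequence as (start, end) pairs (regex)."""
    return [(m.start(), m.end()) for m in re.finditer(r"-+", seq)]


def merged_gap_events(seqs, min_size=1):
    """All distinct identically-placed maximal gap runs across sequences."""
    spans = set()
    for s in seqs:
        spans.update(scan_gap_runs(s))
    return sorted(sp for sp in spans if sp[1] - sp[0] >= min_size)


def fixed_sites(x_seqs, y_seqs):
    """Columns where all called x share one base, all called y another."""
    out = []
    for col in range(len(x_seqs[0])):
        xs = {s[col] for s in x_seqs} & BASES
        ys = {s[col] for s in y_seqs} & BASES
        if len(xs) == 1 and len(ys) == 1 and xs != ys:
            out.append(col)
    return out


def group_snps_by_pattern(seqs, ids):
    """Brute-force mutual-linkage grouping by comparing every column pair's
    bipartition of the called samples (biallelic columns only)."""
    patterns = {}
    for col in range(len(seqs[0])):
        called = [(i, s[col]) for i, s in zip(ids, seqs) if s[col] in BASES]
        alleles = sorted({b for _, b in called})
        if len(alleles) != 2:
            continue
        sides = frozenset({
            frozenset(i for i, b in called if b == alleles[0]),
            frozenset(i for i, b in called if b == alleles[1]),
        })
        patterns.setdefault(sides, []).append(col)
    return {k: tuple(v) for k, v in patterns.items()}
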