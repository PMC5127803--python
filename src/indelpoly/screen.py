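"""Locus-selection screens for indel candidates and loci.

Reimplements the selection funnels used to assemble indel panels from
*Arabidopsis* resources: a Col-0/Ler style screen on indel size, insertion
uniqueness and flanking diversity; resequencing-panel quality criteria for
large indels; long-intergenic-region selection; and the multi-accession
locus filter (accession sampling and locus length).  BLAST uniqueness is
approximated by exact substring occurrence counting on a supplied genome
text (both strands) — an intentional, documented simplification.

Filters are independent, idempotent and depend only on the candidate's
fields; every failure is named.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq

from .alignment_io import Alignment, IndelEvent


@dataclass
class IndelCandidate:
    """One candidate indel with the evidence the screens consume.

    Sequence-derived fields (ambiguous fractions, genome hit count) may be
    supplied directly or computed from the sequences when present.
    ``flank_max_indel_bp`` is the longest indel observed in the 2-kb flanks;
    ``junction_clear`` records whether the deletion junction is uniquely
    placed (see :func:`junction_clearly_identified`).
    """

    id: str
    chromosome: str = ""
    start: int = 0
    end: int = 0
    size: int = 0
    insertion_sequence: str | None = None
    flank_up: str | None = None
    flank_down: str | None = None
    ambiguous_fraction_insert: float | None = None
    ambiguous_fraction_flanks: float | None = None
    genome_hit_count: int | None = None
    flank_diversity: float | None = None
    flank_max_indel_bp: float | None = None
    junction_clear: bool = True

    def __post_init__(self) -> None:
        if self.size == 0 and self.end > self.start:
            self.size = self.end - self.start
        if self.insertion_sequence is not None and self.size == 0:
            self.size = len(self.insertion_sequence)


@dataclass(frozen=True)
class ScreenDecision:
    """Outcome of one screen on one candidate."""

    candidate_id: str
    failed_criteria: tuple

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


def ambiguous_fraction(seq: str, ambiguous: str = "NZ") -> float:
    """Fraction of ambiguous (no-call / zero-coverage) characters."""
    if not seq:
        return 0.0
    up = seq.upper()
    return sum(up.count(c) for c in ambiguous) / len(up)


def count_genome_hits(sequence: str, genome: str) -> int:
    """Overlapping exact occurrences of ``sequence`` in ``genome``, both
    strands (reverse complement included)."""
    seq = sequence.upper()
    gen = genome.upper()
    rc = str(Seq(seq).reverse_complement())
    hits = len(re.findall(f"(?={re.escape(seq)})", gen))
    if rc != seq:
        hits += len(re.findall(f"(?={re.escape(rc)})", gen))
    return hits


def junction_clearly_identified(alignment: Alignment, event: IndelEvent,
                                tol: int = 10) -> bool:
    """A deletion junction is 'clearly identified' when no alternative
    maximal gap run places a boundary within ``tol`` bp of the event's
    boundaries (unique breakpoint placement)."""
    from . import alignment_io as aio
    for other in aio.extract_indels(alignment, min_size=1):
        if other.span == event.span:
            continue
        for b in (other.start, other.end):
            if (abs(b - event.start) <= tol or abs(b - event.end) <= tol):
                return False
    return True


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def screen_jander_style(candidates: Iterable[IndelCandidate],
                        size_range: tuple = (100, 2000),
                        flank_div_range: tuple = (0.01, 0.05),
                        genome: str | None = None) -> list:
    """Col/Ler-style indel screen.

    Rules (each named on failure): indel size strictly greater than
    ``size_range[0]`` and at most ``size_range[1]``; insertion sequence
    unique in the genome (exact-occurrence count <= 1, both strands);
    flanking diversity between the designated accession pair within
    ``flank_div_range`` (inclusive).  Candidates lacking flank data fail
    with ``unavailable_sequence``.
    """
    lo, hi = size_range
    decisions = []
    for c in candidates:
        failed = []
        if not (lo < c.size <= hi):
            failed.append("size")
        hit_count = c.genome_hit_count
        if hit_count is None and genome is not None and c.insertion_sequence:
            hit_count = count_genome_hits(c.insertion_sequence, genome)
        if hit_count is not None and hit_count > 1:
            failed.append("uniqueness")
        if c.flank_diversity is None:
            failed.append("unavailable_sequence")
        elif not (flank_div_range[0] <= c.flank_diversity <= flank_div_range[1]):
            failed.append("flank_diversity")
        decisions.append(ScreenDecision(c.id, tuple(failed)))
    return decisions


def screen_1001_style(candidate: IndelCandidate) -> ScreenDecision:
    """Resequencing-panel quality criteria for large indels, named 1-5:

    1. size > 100 bp;
    2. the deletion junction is clearly identified (unique boundary);
    3. no indel longer than 10 bp in the 2-kb flanks;
    4. insertion sequence <= 1% ambiguous nucleotides;
    5. flanking sequences <= 5% ambiguous nucleotides.
    """
    failed = []
    if not candidate.size > 100:
        failed.append("1")
    if not candidate.junction_clear:
        failed.append("2")
    if candidate.flank_max_indel_bp is not None and candidate.flank_max_indel_bp > 10:
        failed.append("3")
    frac_ins = candidate.ambiguous_fraction_insert
    if frac_ins is None and candidate.insertion_sequence is not None:
        frac_ins = ambiguous_fraction(candidate.insertion_sequence)
    if frac_ins is not None and frac_ins > 0.01:
        failed.append("4")
    frac_fl = candidate.ambiguous_fraction_flanks
    if frac_fl is None and (candidate.flank_up or candidate.flank_down):
        combined = (candidate.flank_up or "") + (candidate.flank_down or "")
        frac_fl = ambiguous_fraction(combined)
    if frac_fl is not None and frac_fl > 0.05:
        failed.append("5")
    return ScreenDecision(candidate.id, tuple(failed))


@dataclass(frozen=True)
class IntergenicRegion:
    id: str
    length_bp: int
    repeat_fraction: float


def screen_long_intergenic(regions: Iterable[IntergenicRegion],
                           min_length: int = 8000,
                           max_repeat_fraction: float = 0.15) -> list:
    """Long-intergenic selection: length > 8 kb (strict) and repeat
    fraction < 15% (strict)."""
    decisions = []
    for r in regions:
        failed = []
        if not r.length_bp > min_length:
            failed.append("length")
        if not r.repeat_fraction < max_repeat_fraction:
            failed.append("repeat_fraction")
        decisions.append(ScreenDecision(r.id, tuple(failed)))
    return decisions


def nordborg_locus_filter(locus_id: str, n_accessions: int, length_bp: int,
                          min_accessions: int = 60, min_length: int = 400) -> ScreenDecision:
    """Multi-accession locus filter: >= 60 accessions and >= 400 bp."""
    failed = []
    if n_accessions < min_accessions:
        failed.append("accessions")
    if length_bp < min_length:
        failed.append("length")
    return ScreenDecision(locus_id, tuple(failed))


def write_decisions(decisions: Iterable[ScreenDecision], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("candidate\tpassed\tfailed_criteria\n")
        for d in decisions:
            fh.write(f"{d.candidate_id}\t{int(d.passed)}\t"
                     f"{','.join(d.failed_criteria) or '.'}\n")
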