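"""Aligned-locus I/O, indel detection, junction extraction and masking.

A locus is a multi-accession alignment (aligned FASTA, one file per locus)
over the alphabet ``A C G T - N``: ``-`` marks alignment gaps (insertion /
deletion polymorphism) and ``N`` marks uncalled bases.  All statistics
downstream treat ``-`` and ``N`` as *uncalled*; a column enters statistics
only if at least 90% of samples are called there.

Coordinates are 0-based with half-open ``[start, end)`` intervals.  The
distance from a column to an indel is the number of columns strictly
between the column and the nearest span boundary (adjacent column at
distance 0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = ord("-")
AMBIG = ord("N")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_VALID_BYTES = frozenset(b"ACGTN-")

#: a column is retained for statistics iff called fraction >= this
MIN_CALLED_FRACTION = 0.90


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged records, bad characters, empty file)."""


@dataclass(eq=False)
class Alignment:
    """A multi-accession locus alignment.

    Parameters
    ----------
    locus_id:
        Locus name (defaults to the file stem on load).
    sample_ids:
        Ordered, unique accession names, one per row.
    matrix:
        ``(n, L)`` uint8 array of ASCII codes over ``ACGTN-``.
    masked_columns:
        Number of columns replaced by ``N`` by :func:`mask_fixed_indels`.
    fixed_indel_count:
        Number of gap-run events masked by :func:`mask_fixed_indels`.
    truncated:
        Set on junction regions that could not reach their full width.
    source_columns:
        For sub-alignments, the parent column index of each column.
    """

    locus_id: str
    sample_ids: tuple
    matrix: np.ndarray
    coordinate_origin: int = 0
    masked_columns: int = 0
    fixed_indel_count: int = 0
    truncated: bool = False
    source_columns: tuple | None = None

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentFormatError("one sample id required per row")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentFormatError("sample ids must be unique")
        if self.n < 2:
            raise AlignmentFormatError("an alignment needs at least 2 samples")
        bad = set(self.matrix.tobytes()) - _VALID_BYTES
        if bad:
            raise AlignmentFormatError(
                "invalid characters in alignment: %r" % sorted(chr(b) for b in bad)
            )

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> str:
        return self.matrix[self.sample_ids.index(sample_id)].tobytes().decode()

    def sequences(self) -> list:
        return [self.matrix[i].tobytes().decode() for i in range(self.n)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.locus_id == other.locus_id
            and self.sample_ids == other.sample_ids
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )

    def subset_columns(self, columns: Sequence[int], locus_id: str | None = None,
                       truncated: bool = False) -> "Alignment":
        cols = np.asarray(columns, dtype=np.intp)
        return Alignment(
            locus_id=locus_id or self.locus_id,
            sample_ids=self.sample_ids,
            matrix=self.matrix[:, cols],
            truncated=truncated,
            source_columns=tuple(int(c) for c in cols),
        )

    @classmethod
    def from_sequences(cls, locus_id: str, sample_ids: Iterable[str],
                       sequences: Iterable[str]) -> "Alignment":
        seqs = [s.upper() for s in sequences]
        lens = {len(s) for s in seqs}
        if len(lens) != 1:
            raise AlignmentFormatError("sequences have unequal lengths")
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
        return cls(locus_id, tuple(sample_ids), mat.reshape(len(seqs), lens.pop()))


@dataclass(frozen=True)
class IndelEvent:
    """One insertion/deletion polymorphism: a maximal gap run shared
    (identically placed) by one or more samples.

    ``presence`` holds one state per sample, in alignment row order:
    ``P`` (sequence present), ``A`` (gapped across the full span) or ``U``
    (partially gapped or N-covered).  ``kind`` is ``insertion``/``deletion``
    relative to a named reference sample, or ``None`` if no reference was
    given or the reference state is unknown.
    """

    locus_id: str
    start: int
    end: int
    presence: tuple
    kind: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("indel span must satisfy 0 <= start < end")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> tuple:
        return (self.start, self.end)

    def present_ids(self, sample_ids: Sequence[str]) -> tuple:
        return tuple(s for s, p in zip(sample_ids, self.presence) if p == "P")

    def absent_ids(self, sample_ids: Sequence[str]) -> tuple:
        return tuple(s for s, p in zip(sample_ids, self.presence) if p == "A")

    def unknown_ids(self, sample_ids: Sequence[str]) -> tuple:
        return tuple(s for s, p in zip(sample_ids, self.presence) if p == "U")

    @property
    def is_polymorphic(self) -> bool:
        return "P" in self.presence and "A" in self.presence

    def distance_to_column(self, column: int) -> int:
        """Columns strictly between ``column`` and the span (0 if adjacent/inside)."""
        if column < self.start:
            return self.start - 1 - column
        if column >= self.end:
            return column - self.end
        return 0


@dataclass(frozen=True)
class SiteClass:
    """Classification of one alignment column."""

    column: int
    site_class: str  # monomorphic | SNP | gap | ambiguous
    alleles: str     # per-sample characters, row order


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(path, locus_id: str | None = None) -> Alignment:
    """Read one locus from aligned FASTA.

    Raises :class:`AlignmentFormatError` naming the offending record when
    records differ in length, and on empty files.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    length = len(records[0].seq)
    for rec in records[1:]:
        if len(rec.seq) != length:
            raise AlignmentFormatError(
                f"{path}: record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )
    return Alignment.from_sequences(
        locus_id or path.stem,
        [rec.id for rec in records],
        [str(rec.seq) for rec in records],
    )


def write_alignment(alignment: Alignment, path, width: int = 60) -> None:
    """Write aligned FASTA (uppercase, fixed line width; deterministic)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.sample_ids, alignment.sequences())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# site bookkeeping
# ---------------------------------------------------------------------------

def called_mask(alignment: Alignment) -> np.ndarray:
    """Boolean ``(n, L)`` mask of called (A/C/G/T) cells."""
    return np.isin(alignment.matrix, _BASE_BYTES)


def retained_columns(alignment: Alignment) -> np.ndarray:
    """Columns entering statistics: called fraction >= 90%."""
    frac = called_mask(alignment).mean(axis=0)
    return np.flatnonzero(frac + 1e-12 >= MIN_CALLED_FRACTION)


def effective_length(alignment: Alignment) -> int:
    """Number of callable (retained) columns."""
    return int(retained_columns(alignment).size)


def classify_sites(alignment: Alignment) -> list:
    """Classify every column.

    ``ambiguous``: more than 10% of samples uncalled (excluded from all
    statistics); ``SNP``: >= 2 distinct called bases; ``gap``: monomorphic
    among called samples but gapped in some; ``monomorphic`` otherwise.
    """
    mat = alignment.matrix
    called = called_mask(alignment)
    retained = set(retained_columns(alignment).tolist())
    out = []
    for col in range(alignment.length):
        alleles = mat[:, col].tobytes().decode()
        if col not in retained:
            cls = "ambiguous"
        else:
            bases = {c for c, ok in zip(alleles, called[:, col]) if ok}
            if len(bases) >= 2:
                cls = "SNP"
            elif "-" in alleles:
                cls = "gap"
            else:
                cls = "monomorphic"
        out.append(SiteClass(col, cls, alleles))
    return out


# ---------------------------------------------------------------------------
# indel detection
# ---------------------------------------------------------------------------

def _gap_runs(row: np.ndarray) -> list:
    """Maximal runs of '-' in one row as [start, end) pairs."""
    isgap = np.concatenate(([False], row == GAP, [False]))
    edges = np.flatnonzero(np.diff(isgap.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def extract_indels(alignment: Alignment, min_size: int = 1,
                   ref: str | None = None) -> list:
    """Detect indel events as identically-placed maximal gap runs.

    One event per distinct ``(start, end)`` maximal run observed in any
    sample; events smaller than ``min_size`` are dropped.  Near-identical
    overlapping runs are distinct events (co-located different-size indels
    stay separate).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mat = alignment.matrix
    spans = set()
    for i in range(alignment.n):
        spans.update(_gap_runs(mat[i]))
    ref_idx = alignment.sample_ids.index(ref) if ref is not None else None
    events = []
    for start, end in sorted(spans):
        if end - start < min_size:
            continue
        presence = []
        for i in range(alignment.n):
            seg = mat[i, start:end]
            gaps = seg == GAP
            if gaps.all():
                presence.append("A")
            elif gaps.any() or (seg == AMBIG).any():
                presence.append("U")
            else:
                presence.append("P")
        kind = None
        if ref_idx is not None:
            state = presence[ref_idx]
            kind = {"P": "deletion", "A": "insertion"}.get(state)
        events.append(IndelEvent(alignment.locus_id, start, end, tuple(presence), kind))
    return events


def junction_columns(alignment: Alignment, event: IndelEvent, flank: int = 300) -> np.ndarray:
    """Column indices of the junction region: up to ``2*flank`` non-indel
    columns around the event span, redistributing the deficit when one side
    is truncated at a locus edge."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if event.locus_id != alignment.locus_id or event.end > alignment.length:
        raise ValueError(f"event {event.span} does not belong to locus {alignment.locus_id!r}")
    left = np.arange(0, event.start, dtype=np.intp)
    right = np.arange(event.end, alignment.length, dtype=np.intp)
    total = min(2 * flank, left.size + right.size)
    left_take = min(left.size, max(flank, total - right.size))
    right_take = total - left_take
    return np.concatenate([left[left.size - left_take:], right[:right_take]])


def junction_region(alignment: Alignment, event: IndelEvent, flank: int = 300) -> Alignment:
    """Sub-alignment of the ~``2*flank`` bp surrounding the deletion
    junction (indel columns excluded; default 300 bp per side -> ~600 bp).

    The result is flagged ``truncated`` when the locus edges leave fewer
    than ``2*flank`` columns.
    """
    cols = junction_columns(alignment, event, flank)
    return alignment.subset_columns(
        cols,
        locus_id=f"{alignment.locus_id}:JR@{event.start}",
        truncated=cols.size < 2 * flank,
    )


def mask_fixed_indels(alignment: Alignment, partition) -> Alignment:
    """Mask (to ``N``) every gap-run event fixed between the two haplogroups.

    An event is fixed when its presence states are internally uniform in
    each haplogroup (unknowns ignored) and the two groups differ.  Masked
    columns become uncalled for every sample, so the effective length drops
    by the number of masked columns.  ``partition`` is any object with
    ``x_members``/``y_members`` id collections.
    """
    events = extract_indels(alignment, min_size=1)
    idx = {s: i for i, s in enumerate(alignment.sample_ids)}
    col_mask = np.zeros(alignment.length, dtype=bool)
    n_fixed = 0
    for ev in events:
        xs = {ev.presence[idx[s]] for s in partition.x_members} - {"U"}
        ys = {ev.presence[idx[s]] for s in partition.y_members} - {"U"}
        if len(xs) == 1 and len(ys) == 1 and xs != ys:
            col_mask[ev.start:ev.end] = True
            n_fixed += 1
    new = alignment.matrix.copy()
    new[:, col_mask] = AMBIG
    return dataclasses.replace(
        alignment,
        matrix=new,
        masked_columns=int(col_mask.sum()),
        fixed_indel_count=n_fixed,
    )


# ---------------------------------------------------------------------------
# indel tables (6-column TSV)
# ---------------------------------------------------------------------------

def write_indel_table(events: Iterable[IndelEvent], path, header: str = "") -> None:
    """Write events as TSV: locus, start, end, size, kind, presence (P/A/U
    per sample, row order)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("locus\tstart\tend\tsize\tkind\tpresence\n")
        for ev in events:
            fh.write(
                f"{ev.locus_id}\t{ev.start}\t{ev.end}\t{ev.size}\t"
                f"{ev.kind or '.'}\t{''.join(ev.presence)}\n"
            )


def read_indel_table(path) -> list:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("locus\t") or not line.strip():
                continue
            locus, start, end, _size, kind, presence = line.rstrip("\n").split("\t")
            events.append(IndelEvent(locus, int(start), int(end), tuple(presence),
                                     None if kind == "." else kind))
    return events
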