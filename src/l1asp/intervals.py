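"""Genomic-interval data model, overlap engine, and strand resolution.

All coordinates are 0-based half-open (BED convention).  Conversion to the
1-based inclusive dialect used in printed reports happens only at the I/O
boundary (see :mod:`l1asp.motifs.report_sites` and the table writers).

The central subtlety of spliced-EST tables is that the record strand is the
*alignment* strand (the direction the cDNA aligned to the genome), not the
transcriptional direction.  A separate per-record signed integer — the
``intronOrientation`` semantic — says whether splice-site dinucleotides
support transcription in the alignment direction (positive), the opposite
direction (negative), or neither (zero, undetermined).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_UNKNOWN = "."
UNDETERMINED = "undetermined"

_OPPOSITE = {STRAND_PLUS: STRAND_MINUS, STRAND_MINUS: STRAND_PLUS}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Strand-blind overlap in base pairs; 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class SplicedTranscript:
    """One spliced alignment record (BED12-like) plus orientation metadata.

    ``blocks`` are the aligned exon blocks, sorted by start, non-overlapping,
    spanning exactly ``[align_start, align_end)``.  ``txn_strand`` is the
    resolved transcriptional direction ("+", "-" or "undetermined")."""

    id: str
    chrom: str
    align_start: int
    align_end: int
    align_strand: str
    blocks: tuple[GenomicInterval, ...]
    intron_orientation: int = 0
    txn_strand: str = UNDETERMINED
    n_alignments: int = 1

    def __post_init__(self) -> None:
        if self.align_strand not in _OPPOSITE:
            raise ValueError(f"bad alignment strand {self.align_strand!r}")
        if not self.blocks:
            raise ValueError(f"{self.id}: no blocks")
        prev_end = None
        for b in self.blocks:
            if b.chrom != self.chrom:
                raise ValueError(f"{self.id}: block on wrong chromosome")
            if prev_end is not None and b.start < prev_end:
                raise ValueError(f"{self.id}: blocks unsorted or overlapping")
            prev_end = b.end
        if self.blocks[0].start != self.align_start or self.blocks[-1].end != self.align_end:
            raise ValueError(f"{self.id}: blocks do not span the alignment")
        if self.n_alignments < 1:
            raise ValueError(f"{self.id}: n_alignments must be >= 1")

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) >= 2

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.align_start, self.align_end, self.align_strand)


def resolve_txn_strand(t: SplicedTranscript) -> SplicedTranscript:
    """Resolve the transcriptional direction from the intron-orientation field.

    Positive: transcription matches the alignment strand.  Negative: opposite.
    Zero: undetermined (not an error; such records are dropped downstream).
    Idempotent: re-resolving a resolved record yields an equal record.
    """
    if t.intron_orientation > 0:
        strand = t.align_strand
    elif t.intron_orientation < 0:
        strand = _OPPOSITE[t.align_strand]
    else:
        strand = UNDETERMINED
    return replace(t, txn_strand=strand)


class UnresolvedStrandError(ValueError):
    """Raised when an operation needs a resolved transcription strand."""


def tss_of(t: SplicedTranscript) -> GenomicInterval:
    """The 1-bp interval holding the transcript's 5' start.

    For a plus-strand transcript this is the alignment start; for a
    minus-strand transcript the last aligned base.
    """
    if t.txn_strand == STRAND_PLUS:
        pos = t.align_start
    elif t.txn_strand == STRAND_MINUS:
        pos = t.align_end - 1
    else:
        raise UnresolvedStrandError(
            f"{t.id}: transcription strand undetermined; cannot place TSS"
        )
    return GenomicInterval(t.chrom, pos, pos + 1, t.txn_strand)


@dataclass(frozen=True)
class RepeatElement:
    """A RepeatMasker-style repeat annotation interval."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid repeat interval [{self.start}, {self.end})")
        if self.strand not in _OPPOSITE:
            raise ValueError(f"repeat {self.subfamily}: strand must be + or -")
        if not self.family:
            raise ValueError(f"repeat {self.subfamily}: empty family")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def key(self) -> tuple[str, int, int, str]:
        """A stable identity for an annotation row (used for exonization vetoes)."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon intervals; TSS derived from strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in _OPPOSITE:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        prev_end = None
        for e in self.exons:
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e.end

    @property
    def tss(self) -> int:
        if self.strand == STRAND_PLUS:
            return self.exons[0].start
        return self.exons[-1].end - 1


class IntervalIndex:
    """Chromosome-partitioned interval tree over a fixed interval list.

    Query results are lists of indices into the original list, sorted."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self.intervals = list(intervals)
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    def query(self, iv: GenomicInterval) -> list[int]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(iv.start, iv.end))

    def query_point(self, chrom: str, pos: int) -> list[int]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(pos))


def bulk_intersect(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs with positive overlap.

    Deterministic output order: sorted by query index, then subject index.
    """
    index = IntervalIndex(subject)
    pairs: list[tuple[int, int]] = []
    for qi, q in enumerate(query):
        for si in index.query(q):
            pairs.append((qi, si))
    return pairs
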