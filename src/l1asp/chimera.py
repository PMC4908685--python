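"""The three-criterion screen for L1 antisense-promoter chimeric transcripts.

A transcript is accepted when

* C1 — its TSS lies inside an annotated L1 element and its transcriptional
  direction is antisense to that element (the L1 antisense promoter drives
  it);
* C2 — at least one of its aligned blocks overlaps an annotated exon of a
  gene (it is chimeric: L1 5' end spliced to genic sequence);
* C3 — no *independent* transcript (different record id) supports
  exonization of the same anchor L1, i.e. an exon–L1–exon structure where
  the antisense L1 is an internal exon rather than the transcript 5' end.

C3 guards against the classic confounder: gene transcripts can retain an
intronic antisense L1 through cryptic splice sites, which mimics antisense-
promoter initiation when only partial cDNA alignments are available.

Accepted calls are annotated with the L1 subfamily age class, a per-gene
orientation and TSS-distance record, and a multi-alignment flag (records
with several alignments are flagged, never removed).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    RepeatElement,
    SplicedTranscript,
    UNDETERMINED,
    overlap_bp,
    resolve_txn_strand,
    tss_of,
)

L1HS = "L1HS"
L1PA2_8 = "L1PA2_8"
ANCIENT_PRIMATE = "ancient_primate"
ANCIENT_MAMMALIAN = "ancient_mammalian"
SUBFAMILY_CLASSES = (L1HS, L1PA2_8, ANCIENT_PRIMATE, ANCIENT_MAMMALIAN)

_PA_NUM = re.compile(r"^L1PA(\d+)")


class SubfamilyClassMap:
    """Ordered rules mapping an L1 subfamily name to an age class.

    The default map bins names into the four classes used throughout:
    human-specific L1HS (plus its synonym L1PA1), recent primate L1PA2-8,
    any other primate-lineage name (L1PA*, L1PB*, L1P*), and everything
    else in the L1 family (L1M*, L1ME*, HAL1* ...) as ancient mammalian.
    Custom maps may be supplied as an explicit name -> class dict.
    """

    def __init__(self, explicit: Optional[dict[str, str]] = None):
        self.explicit = dict(explicit) if explicit else None

    def classify(self, name: str) -> str:
        if self.explicit is not None:
            try:
                return self.explicit[name]
            except KeyError:
                raise KeyError(f"subfamily {name!r} missing from the class map") from None
        if name in ("L1HS", "L1PA1"):
            return L1HS
        m = _PA_NUM.match(name)
        if m and 2 <= int(m.group(1)) <= 8:
            return L1PA2_8
        if name.startswith(("L1PA", "L1PB", "L1P")):
            return ANCIENT_PRIMATE
        if name.startswith(("L1", "HAL1")):
            return ANCIENT_MAMMALIAN
        raise KeyError(f"subfamily {name!r} does not look like an L1-family name")


def classify_subfamily(name: str, class_map: Optional[SubfamilyClassMap] = None) -> str:
    """Map an L1 subfamily name (e.g. L1HS, L1PA5, L1M5) to its age class."""
    return (class_map or SubfamilyClassMap()).classify(name)


@dataclass(frozen=True)
class PairwiseOverlap:
    """One transcript-gene exon overlap with orientation and TSS distance.

    ``tss_distance`` is signed base pairs from the gene TSS to the transcript
    TSS, positive = downstream in the gene's orientation."""

    gene_id: str
    relative_orientation: str  # "sense" | "antisense"
    tss_distance: int
    overlap_bp: int


@dataclass
class ChimeraCall:
    """One accepted (or exonization-removed) transcript-L1 anchor."""

    transcript_id: str
    anchor: RepeatElement
    tss: int
    txn_strand: str
    subfamily_class: str
    gene_overlaps: list[PairwiseOverlap]
    multi_alignment: bool = False
    excluded_by_exonization: bool = False


@dataclass
class ScreenResult:
    accepted: list[ChimeraCall]
    removed_exonization: list[ChimeraCall]
    dropped_zero_orientation: int
    n_input: int = 0

    @property
    def accepted_ids(self) -> set[str]:
        return {c.transcript_id for c in self.accepted}


def annotate_gene_overlap(
    txn_strand: str, transcript_tss: int, gene: GeneModel, ov_bp: int
) -> PairwiseOverlap:
    """Orientation and TSS distance of one transcript-gene overlap."""
    orientation = "sense" if txn_strand == gene.strand else "antisense"
    distance = transcript_tss - gene.tss
    if gene.strand == "-":
        distance = -distance
    return PairwiseOverlap(
        gene_id=gene.gene_id,
        relative_orientation=orientation,
        tss_distance=distance,
        overlap_bp=ov_bp,
    )


def is_exonization_support(t: SplicedTranscript, l1: RepeatElement) -> bool:
    """Does ``t`` show the exon–L1–exon structure over the antisense L1?

    True iff the transcript runs antisense to the element, at least one
    block overlaps it, and at least one block lies entirely on each side of
    the L1-overlapping blocks — so the L1 is internal to the transcript, not
    its 5' end.
    """
    if t.txn_strand == UNDETERMINED:
        return False
    if t.txn_strand == l1.strand:
        return False
    liv = l1.interval
    ov = [i for i, b in enumerate(t.blocks) if overlap_bp(b, liv) > 0]
    if not ov:
        return False
    return min(ov) >= 1 and max(ov) <= len(t.blocks) - 2


def _choose_anchor(
    tss: GenomicInterval,
    tss_block: GenomicInterval,
    candidates: list[RepeatElement],
) -> Optional[RepeatElement]:
    """Pick the anchor L1 for a TSS falling inside >= 1 antisense elements.

    Larger overlap with the TSS-containing block wins; ties go to the
    element with the smaller start.  Deterministic by construction.
    """
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda r: (overlap_bp(r.interval, tss_block), -r.start),
    )


def screen(
    transcripts: Sequence[SplicedTranscript],
    repeats: Sequence[RepeatElement],
    genes: Sequence[GeneModel],
    class_map: Optional[SubfamilyClassMap] = None,
    min_exon_overlap: int = 1,
) -> ScreenResult:
    """Run the full three-criterion screen.

    Transcription strands are resolved from the intron-orientation field
    (idempotent for already-resolved records); records with orientation zero
    are dropped and counted.  Only spliced records (>= 2 blocks) enter the
    screen.  Repeats should be the L1-family annotation; elements of other
    families are ignored for anchoring but also never veto.
    """
    cmap = class_map or SubfamilyClassMap()
    resolved = [resolve_txn_strand(t) for t in transcripts]
    dropped_zero = sum(1 for t in resolved if t.txn_strand == UNDETERMINED)
    usable = [t for t in resolved if t.txn_strand != UNDETERMINED and t.is_spliced]

    repeat_index = IntervalIndex([r.interval for r in repeats])
    exon_ivs: list[GenomicInterval] = []
    exon_gene: list[int] = []
    for gi, g in enumerate(genes):
        for e in g.exons:
            exon_ivs.append(e)
            exon_gene.append(gi)
    exon_index = IntervalIndex(exon_ivs)

    # C1 + C2: candidate calls
    candidates: list[tuple[SplicedTranscript, ChimeraCall]] = []
    for t in usable:
        tss = tss_of(t)
        hits = [
            repeats[i]
            for i in repeat_index.query_point(t.chrom, tss.start)
            if repeats[i].strand != t.txn_strand
        ]
        tss_block = next(b for b in t.blocks if b.contains(tss.start))
        anchor = _choose_anchor(tss, tss_block, hits)
        if anchor is None:
            continue
        per_gene: dict[int, int] = {}
        for b in t.blocks:
            for ei in exon_index.query(b):
                per_gene[exon_gene[ei]] = per_gene.get(exon_gene[ei], 0) + overlap_bp(
                    b, exon_ivs[ei]
                )
        overlaps = [
            annotate_gene_overlap(t.txn_strand, tss.start, genes[gi], ov)
            for gi, ov in sorted(per_gene.items())
            if ov >= min_exon_overlap
        ]
        if not overlaps:
            continue
        candidates.append(
            (
                t,
                ChimeraCall(
                    transcript_id=t.id,
                    anchor=anchor,
                    tss=tss.start,
                    txn_strand=t.txn_strand,
                    subfamily_class=cmap.classify(anchor.subfamily),
                    gene_overlaps=overlaps,
                    multi_alignment=t.n_alignments > 1,
                ),
            )
        )

    # C3: per-anchor exonization veto by independent (different-id) records
    anchor_keys = {call.anchor.key() for _, call in candidates}
    anchor_by_key = {call.anchor.key(): call.anchor for _, call in candidates}
    supporters: dict[tuple, set[str]] = {k: set() for k in anchor_keys}
    for t in usable:
        for key, l1 in anchor_by_key.items():
            if t.chrom == l1.chrom and is_exonization_support(t, l1):
                supporters[key].add(t.id)

    accepted, removed = [], []
    for t, call in sorted(candidates, key=lambda tc: (tc[1].transcript_id, tc[1].tss)):
        veto = supporters[call.anchor.key()] - {t.id}
        if veto:
            call.excluded_by_exonization = True
            removed.append(call)
        else:
            accepted.append(call)
    return ScreenResult(
        accepted=accepted,
        removed_exonization=removed,
        dropped_zero_orientation=dropped_zero,
        n_input=len(transcripts),
    )


@dataclass
class ScreenSummary:
    n_accepted: int
    per_gene_est_counts: dict[str, int]
    subfamily_class_counts: dict[str, int]
    sense_overlaps: int
    antisense_overlaps: int
    n_multi_alignment: int

    @property
    def n_pairwise_overlaps(self) -> int:
        return self.sense_overlaps + self.antisense_overlaps


def tally(accepted: Sequence[ChimeraCall]) -> ScreenSummary:
    """Aggregate accepted calls: per-gene EST counts, age-class counts,
    sense/antisense pairwise-overlap counts, multi-alignment count."""
    per_gene: Counter = Counter()
    classes: Counter = Counter({c: 0 for c in SUBFAMILY_CLASSES})
    sense = antisense = 0
    for call in accepted:
        classes[call.subfamily_class] += 1
        for ov in call.gene_overlaps:
            per_gene[ov.gene_id] += 1
            if ov.relative_orientation == "sense":
                sense += 1
            else:
                antisense += 1
    return ScreenSummary(
        n_accepted=len(accepted),
        per_gene_est_counts=dict(per_gene),
        subfamily_class_counts=dict(classes),
        sense_overlaps=sense,
        antisense_overlaps=antisense,
        n_multi_alignment=sum(1 for c in accepted if c.multi_alignment),
    )


def validate_with_isoforms(
    est_result: ScreenResult, isoform_result: ScreenResult
) -> set[str]:
    """Cross-platform validation: genes recovered by both screens.

    The same screen is run on a second transcript set (e.g. long-read
    isoform predictions) and the accepted gene sets are intersected.
    """

    def genes_of(res: ScreenResult) -> set[str]:
        return {ov.gene_id for c in res.accepted for ov in c.gene_overlaps}

    return genes_of(est_result) & genes_of(isoform_result)
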