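"""Mapping transcript 5' ends onto full-length L1 consensus sequences.

Chimeric transcripts initiate inside genomic L1 copies; to ask *where* in
the element the antisense promoter fires, each transcript's 5' region is
locally aligned (Smith-Waterman, affine gaps, both orientations) to the
full-length consensus of its subfamily age class, and the consensus
coordinate matched to the transcript's 5'-most aligned base is expressed as
a percent of the consensus length.  Young-subfamily elements are expected
to fire within the 5' UTR; ancient, typically 5'-truncated elements near
the 3' end.

Gap costs: a gap of length k costs ``gap_open + k * gap_extend`` (the first
gap base pays both the opening and the per-base penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring; defaults suit ~80-99 % identical repeats."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class LocalAlignment:
    """A gapped local alignment of a query to a consensus.

    For ``orientation == "reverse-complement"`` the query coordinates refer
    to the reverse-complemented query sequence; the transcript's 5'-most
    base then maps to ``consensus_end - 1``.
    ``runs`` are gapless segments as (consensus_start, consensus_end,
    query_start, query_end) tuples.
    """

    query_id: str = ""
    consensus_id: str = ""
    score: float = 0.0
    orientation: str = "forward"
    consensus_start: int = 0
    consensus_end: int = 0
    query_start: int = 0
    query_end: int = 0
    runs: tuple[tuple[int, int, int, int], ...] = ()

    @property
    def is_empty(self) -> bool:
        return self.score <= 0.0


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # first gap base pays open + extend
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _align_one(
    aligner: Align.PairwiseAligner, query: str, consensus: str, orientation: str
) -> LocalAlignment:
    score = aligner.score(consensus, query)
    if score <= 0:
        return LocalAlignment(orientation=orientation)
    aln = next(iter(aligner.align(consensus, query)))
    c_ranges, q_ranges = aln.aligned
    runs = tuple(
        (int(cs), int(ce), int(qs), int(qe))
        for (cs, ce), (qs, qe) in zip(c_ranges, q_ranges)
    )
    return LocalAlignment(
        score=float(score),
        orientation=orientation,
        consensus_start=runs[0][0],
        consensus_end=runs[-1][1],
        query_start=runs[0][2],
        query_end=runs[-1][3],
        runs=runs,
    )


def local_align(
    query: str,
    consensus: str,
    scoring: Scoring = Scoring(),
    query_id: str = "",
    consensus_id: str = "",
) -> LocalAlignment:
    """Best local alignment of ``query`` to ``consensus`` over both
    orientations.

    Ties between orientations break toward the smaller consensus start,
    then toward the forward orientation.  If nothing scores above zero an
    empty alignment (score 0) is returned.
    """
    if not query or not consensus:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(scoring)
    fwd = _align_one(aligner, query.upper(), consensus.upper(), "forward")
    rev = _align_one(aligner, revcomp(query.upper()), consensus.upper(), "reverse-complement")
    if fwd.score != rev.score:
        best = fwd if fwd.score > rev.score else rev
    elif fwd.consensus_start != rev.consensus_start:
        best = fwd if fwd.consensus_start < rev.consensus_start else rev
    else:
        best = fwd
    best.query_id = query_id
    best.consensus_id = consensus_id
    return best


def tss_percent_position(aln: LocalAlignment, consensus_length: int) -> float:
    """Percent-of-consensus position of the transcript's 5'-most aligned base.

    Raises on an empty alignment (unmappable TSS; callers count these).
    """
    if aln.is_empty:
        raise ValueError("empty alignment: TSS not mappable onto the consensus")
    if aln.orientation == "forward":
        coord = aln.consensus_start
    else:
        coord = aln.consensus_end - 1
    return 100.0 * coord / consensus_length


@dataclass
class TssPositionProfile:
    """Per-class distribution of TSS percent positions on the consensus."""

    subfamily_class: str
    positions: list[float] = field(default_factory=list)
    unmappable: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.positions)

    def histogram(self, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.positions, bins=n_bins, range=(0.0, 100.0))

    def mode_percent(self, n_bins: int = 20) -> float:
        """Center of the most populated histogram bin."""
        counts, edges = self.histogram(n_bins)
        i = int(np.argmax(counts))
        return float((edges[i] + edges[i + 1]) / 2.0)


def map_tss_position(
    sequence: str,
    consensus: str,
    scoring: Scoring = Scoring(),
    min_score: float = 40.0,
    max_query_nt: int = 1000,
) -> Optional[float]:
    """Align a transcript's 5' region to a consensus and place its TSS.

    Only the first ``max_query_nt`` nucleotides are aligned (the 5' end is
    what is being placed).  Alignments scoring below ``min_score`` are
    treated as unmappable (returns None).
    """
    aln = local_align(sequence[:max_query_nt], consensus, scoring)
    if aln.is_empty or aln.score < min_score:
        return None
    return tss_percent_position(aln, len(consensus))


def build_profile(
    records: Iterable[tuple[str, str, str]],
    consensus_by_class: Mapping[str, str],
    scoring: Scoring = Scoring(),
    min_score: float = 40.0,
    max_query_nt: int = 1000,
) -> dict[str, TssPositionProfile]:
    """TSS percent-position profiles per subfamily age class.

    ``records`` yields (transcript_id, subfamily_class, sequence) triples.
    A missing consensus for a class raises; unmappable transcripts are
    collected per class rather than erroring.
    """
    profiles: dict[str, TssPositionProfile] = {
        cls: TssPositionProfile(cls) for cls in consensus_by_class
    }
    for tid, cls, seq in records:
        if cls not in consensus_by_class:
            raise KeyError(f"no consensus sequence configured for class {cls!r}")
        pos = map_tss_position(
            seq, consensus_by_class[cls], scoring, min_score, max_query_nt
        )
        if pos is None:
            profiles[cls].unmappable.append(tid)
        else:
            profiles[cls].positions.append(pos)
    return profiles
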