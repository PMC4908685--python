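"""ORF calling on transcript sequences and cohort coding-potential summary.

A transcript is called protein-coding when it carries an open reading frame
of at least 100 amino acids that begins with a methionine start codon.
Sequences arrive in transcription orientation, so only the three forward
frames are scanned.  ORFs may be 3'-incomplete (the sequence ends before a
stop codon); these are reported with ``has_stop=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

MIN_CODING_AA = 100
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFPrediction:
    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int  # half-open; includes the stop codon when has_stop
    peptide_length_aa: int
    has_stop: bool
    is_coding_call: bool


def find_orfs(seq: str, transcript_id: str = "", min_coding_aa: int = MIN_CODING_AA) -> list[ORFPrediction]:
    """All maximal ATG-initiated ORFs in the three forward frames.

    Maximal means the ORF starts at the first ATG after the previous stop in
    its frame (later in-frame ATGs start nested, shorter ORFs and are not
    reported).  A codon containing N terminates translation at the preceding
    codon.  Peptide lengths exclude the stop codon.
    """
    seq = seq.upper()
    orfs: list[ORFPrediction] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if "N" in codon:
                # translation cannot continue through an ambiguous codon
                if start is not None and i > start:
                    orfs.append(_make_orf(transcript_id, frame, start, i, False, min_coding_aa))
                start = None
                i += 3
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                orfs.append(_make_orf(transcript_id, frame, start, i + 3, True, min_coding_aa))
                start = None
            i += 3
        if start is not None and i > start:
            orfs.append(_make_orf(transcript_id, frame, start, i, False, min_coding_aa))
    orfs.sort(key=lambda o: (o.start_nt, o.frame))
    return orfs


def _make_orf(
    tid: str, frame: int, start: int, end: int, has_stop: bool, min_coding_aa: int
) -> ORFPrediction:
    aa = (end - start) // 3 - (1 if has_stop else 0)
    return ORFPrediction(
        transcript_id=tid,
        frame=frame,
        start_nt=start,
        end_nt=end,
        peptide_length_aa=aa,
        has_stop=has_stop,
        is_coding_call=aa >= min_coding_aa,
    )


def best_orf(orfs: Sequence[ORFPrediction]) -> ORFPrediction | None:
    """Longest ORF (ties: earliest start)."""
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.peptide_length_aa, -o.start_nt))


@dataclass
class CodingSummary:
    n_transcripts: int
    n_coding: int
    fraction: float
    peptide_mean_aa: float
    peptide_min_aa: int
    peptide_max_aa: int


def coding_fraction(calls_by_transcript: Mapping[str, Sequence[ORFPrediction]]) -> CodingSummary:
    """Fraction of transcripts with a coding call, plus peptide-length stats.

    The peptide statistics are over the best (longest) coding ORF of each
    coding transcript.
    """
    if not calls_by_transcript:
        raise ValueError("empty cohort")
    coding_lengths = []
    for orfs in calls_by_transcript.values():
        coding = [o for o in orfs if o.is_coding_call]
        if coding:
            coding_lengths.append(best_orf(coding).peptide_length_aa)
    n = len(calls_by_transcript)
    k = len(coding_lengths)
    return CodingSummary(
        n_transcripts=n,
        n_coding=k,
        fraction=k / n,
        peptide_mean_aa=float(np.mean(coding_lengths)) if coding_lengths else float("nan"),
        peptide_min_aa=min(coding_lengths) if coding_lengths else 0,
        peptide_max_aa=max(coding_lengths) if coding_lengths else 0,
    )


def call_cohort(sequences: Mapping[str, str], min_coding_aa: int = MIN_CODING_AA) -> dict[str, list[ORFPrediction]]:
    """Run :func:`find_orfs` over a cohort of transcript sequences."""
    return {tid: find_orfs(seq, tid, min_coding_aa) for tid, seq in sequences.items()}
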