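"""Position-weight-matrix scanning with a relative-score threshold.

Counts (JASPAR-style 4 x W matrices, rows A/C/G/T) are turned into a
log-odds matrix after adding a pseudocount proportional to the column sum
and normalizing against a background distribution.  A window's relative
score is ``(score - min) / (max - min)`` where min/max are the matrix's
attainable extremes (sums of per-column minima/maxima) — the convention
used by JASPAR-style scanners, so a 90 % threshold here matches theirs.
Both strands are scanned; minus-strand hits are reported on forward-strand
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """A count matrix plus background and pseudocount policy."""

    motif_id: str
    counts: np.ndarray  # shape (4, W), rows A, C, G, T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount_fraction: float = 0.01  # pseudocount = fraction * column sum

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x W matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.background = np.asarray(self.background, dtype=np.float64)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0)
        pc = self.pseudocount_fraction * colsum
        probs = (self.counts + pc / 4.0) / (colsum + pc)
        return np.log2(probs / self.background[:, None])

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds()
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount_fraction=self.pseudocount_fraction,
        )

    @classmethod
    def from_biopython(cls, motif, **kwargs) -> "PWM":
        counts = np.array([list(motif.counts[b]) for b in BASES], dtype=np.float64)
        return cls(motif_id=motif.matrix_id or motif.name, counts=counts, **kwargs)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: str
    score: float
    relative_score: float


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing non-ACGT get -inf."""
    w = log_odds.shape[1]
    n = len(idx) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        col_idx = idx[j : j + n]
        ok = col_idx >= 0
        valid &= ok
        scores += np.where(ok, log_odds[np.clip(col_idx, 0, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan(
    seq: str,
    pwm: PWM,
    threshold: float = 0.9,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All windows on both strands with relative score >= ``threshold``.

    Hits are sorted by start position (plus strand before minus at equal
    start).  A sequence shorter than the motif yields an empty list.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if len(seq) < pwm.width:
        return []
    idx = _encode(seq)
    lo_f = pwm.log_odds()
    lo_r = pwm.reverse_complement().log_odds()
    smin, smax = pwm.score_range()
    span = smax - smin
    hits = []
    for strand, lo in (("+", lo_f), ("-", lo_r)):
        scores = _window_scores(idx, lo)
        rel = (scores - smin) / span
        for i in np.nonzero(rel >= threshold)[0]:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=int(i),
                    end=int(i) + pwm.width,
                    strand=strand,
                    score=float(scores[i]),
                    relative_score=float(rel[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def report_sites(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Hit table in the 1-based inclusive coordinate dialect of reports.

    A hit spanning [447, 453) half-open is printed as 448 to 453.
    """
    return pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id,
                "start_1based": h.start + 1,
                "end_1based": h.end,
                "strand": h.strand,
                "score": h.score,
                "relative_score": h.relative_score,
            }
            for h in hits
        ],
        columns=[
            "sequence_id",
            "start_1based",
            "end_1based",
            "strand",
            "score",
            "relative_score",
        ],
    )
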