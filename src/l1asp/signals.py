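"""Coverage tracks and TSS metaprofiles for ChIP/input/GRO read sets.

Coverage is computed as read depth per base, normalized to reads per million
mapped reads (RPM) using a supplied library size — the normalizing factor is
the library's total mapped reads, which must come from the full alignment,
not from the regional slice handed to these functions.

Metaprofiles average input-subtracted RPM depth in 100-bp bins over a
+/-1000 bp window around a set of TSSs, oriented so that bin 0 is always
1000 bp *upstream* in transcription direction (minus-strand windows are
reversed before averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

Read = tuple[str, int, int, str]  # (reference, start, end, strand)


@dataclass
class ReadSet:
    """Aligned-read intervals plus the library size used for RPM scaling."""

    reads: list[Read]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < len(self.reads):
            raise ValueError("library_size smaller than the number of records")

    def subset_strand(self, strand: str) -> "ReadSet":
        return ReadSet(
            reads=[r for r in self.reads if r[3] == strand],
            library_size=self.library_size,
        )


@dataclass
class SignalTrack:
    """Per-base values (RPM or log2 fold change) along one reference."""

    reference_id: str
    values: np.ndarray

    @property
    def length(self) -> int:
        return len(self.values)


def coverage_rpm(
    reads: ReadSet, reference_length: int, reference_id: str = ""
) -> SignalTrack:
    """Per-base read depth in RPM on one reference.

    Each supplied record is counted once over its full interval.  Records on
    other references are ignored; intervals are clipped to the reference.
    """
    if reads.library_size <= 0:
        raise ValueError("library_size must be positive")
    diff = np.zeros(reference_length + 1, dtype=np.float64)
    for ref, start, end, _strand in reads.reads:
        if reference_id and ref != reference_id:
            continue
        s = max(0, start)
        e = min(reference_length, end)
        if s < e:
            diff[s] += 1.0
            diff[e] -= 1.0
    depth = np.cumsum(diff[:-1])
    return SignalTrack(reference_id, depth * 1e6 / reads.library_size)


def log2fc_track(chip: SignalTrack, input_: SignalTrack, epsilon: float = 0.25) -> SignalTrack:
    """Per-base log2((chip + eps) / (input + eps)).

    ``epsilon`` (RPM) regularizes zero-coverage bases; default 0.25.
    """
    if chip.length != input_.length:
        raise ValueError("chip and input tracks differ in length")
    values = np.log2((chip.values + epsilon) / (input_.values + epsilon))
    return SignalTrack(chip.reference_id, values)


def loess_smooth(track: SignalTrack, alpha: float = 0.1) -> SignalTrack:
    """LOESS smoothing: degree-1 local regression with tricube weights.

    ``alpha`` is the span — the fraction of points in each local window.
    Reproduces constants and straight lines exactly.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    n = track.length
    if n < 10:
        raise ValueError("track too short to smooth (need >= 10 points)")
    x = np.arange(n, dtype=np.float64)
    smoothed = lowess(track.values, x, frac=alpha, it=0, return_sorted=False)
    return SignalTrack(track.reference_id, np.asarray(smoothed))


@dataclass
class MetaProfile:
    """Binned signal around a TSS set: 20 bins of 100 bp over [-1000, +1000)."""

    bin_edges: np.ndarray
    values: np.ndarray
    n_tss: int
    n_dropped: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def _window_depth_rpm(
    cov_by_ref: dict[str, np.ndarray],
    ref: str,
    pos: int,
    strand: str,
    window: int,
) -> Optional[np.ndarray]:
    cov = cov_by_ref.get(ref)
    if cov is None:
        return None
    lo, hi = pos - window, pos + window
    if lo < 0 or hi > len(cov):
        return None
    win = cov[lo:hi]
    if strand == "-":
        win = win[::-1]
    return win


def tss_metaprofile(
    tss_list: Sequence[tuple[str, int, str]],
    chip: ReadSet,
    input_: Optional[ReadSet],
    reference_lengths: dict[str, int],
    strand_match: bool = False,
    window: int = 1000,
    bin_size: int = 100,
) -> MetaProfile:
    """Average input-subtracted RPM depth in bins around TSSs.

    ``tss_list`` holds (reference, position, strand) triples.  Windows run
    over ``[pos - window, pos + window)``; minus-strand windows are reversed
    so that negative offsets are always upstream of transcription.  TSSs
    whose window leaves the reference are dropped (counted).  With
    ``strand_match`` only reads on the TSS strand are counted — the
    strand-split mode used for nascent-transcription (GRO) reads.
    """
    if (2 * window) % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    n_bins = (2 * window) // bin_size

    def cov_tracks(rs: ReadSet, strand: Optional[str]) -> dict[str, np.ndarray]:
        use = rs.subset_strand(strand) if strand else rs
        return {
            ref: coverage_rpm(use, length, ref).values
            for ref, length in reference_lengths.items()
        }

    per_tss = []
    n_dropped = 0
    strands_needed = sorted({s for _, _, s in tss_list}) if strand_match else [None]
    chip_cov = {s: cov_tracks(chip, s) for s in strands_needed}
    input_cov = {s: cov_tracks(input_, s) for s in strands_needed} if input_ else None

    for ref, pos, strand in tss_list:
        key = strand if strand_match else None
        win = _window_depth_rpm(chip_cov[key], ref, pos, strand, window)
        if win is None:
            n_dropped += 1
            continue
        binned = win.reshape(n_bins, bin_size).mean(axis=1)
        if input_cov is not None:
            iwin = _window_depth_rpm(input_cov[key], ref, pos, strand, window)
            if iwin is None:
                n_dropped += 1
                continue
            binned = binned - iwin.reshape(n_bins, bin_size).mean(axis=1)
        per_tss.append(binned)

    edges = np.arange(-window, window + bin_size, bin_size, dtype=np.float64)
    if not per_tss:
        return MetaProfile(edges, np.zeros(n_bins), 0, n_dropped)
    return MetaProfile(edges, np.vstack(per_tss).mean(axis=0), len(per_tss), n_dropped)
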