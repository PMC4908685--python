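"""Synthetic genomes, annotations, spliced alignments and read sets with
known ground truth.

The generator emulates the statistical structure the chimera screen
assumes: a genome carrying L1 elements whose sequence derives from a
subfamily-class consensus (young elements full length, ancient elements 5'
truncated and more diverged), genes with exons, and spliced alignment
records with alignment-strand/orientation metadata.  Planted record types:

* true chimeras — TSS inside an antisense L1 (young classes within the
  first 600 consensus bp, mimicking 5' UTR antisense-promoter firing;
  ancient classes in the final 20 % of the element), spliced into a
  downstream gene exon;
* exonization decoys — a chimera-like candidate plus an *independent*
  record with the exon-L1-exon structure over the same element, so the
  candidate must be removed by the screen's third criterion;
* plain gene ESTs, records with orientation zero (undetermined strand),
  and multi-alignment records (a second alignment of the same id at a
  barren locus);
* promoter-shaped read pileups immediately downstream of every planted TSS
  (strand-aware, GRO-like) plus uniform input reads;
* consensus-aligned read pileups and planted motif sites in the young-class
  consensus "5' UTR" for the PWM-scanning and per-bp track stages.

Transcript sequences are consistent with their genomic blocks, so the same
records the screen accepts feed consensus TSS mapping and ORF calling.
Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .chimera import (
    ANCIENT_MAMMALIAN,
    ANCIENT_PRIMATE,
    L1HS,
    L1PA2_8,
    SUBFAMILY_CLASSES,
)
from .intervals import GeneModel, GenomicInterval, RepeatElement, SplicedTranscript
from .orfs import find_orfs
from .signals import ReadSet
from . import io as lio

_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_SUBFAMILY_NAMES = {
    L1HS: ["L1HS"],
    L1PA2_8: ["L1PA2", "L1PA3", "L1PA4", "L1PA5", "L1PA6", "L1PA7", "L1PA8"],
    ANCIENT_PRIMATE: ["L1PA10", "L1PA13", "L1PB1", "L1P2"],
    ANCIENT_MAMMALIAN: ["L1M5", "L1M4", "L1ME1", "L1MA9", "HAL1"],
}
_YOUNG = (L1HS, L1PA2_8)

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Counts default to the standard benchmarking cohort (50 chimeras, 20
    exonization decoys, 30 plain gene ESTs, 5 zero-orientation and 5
    multi-alignment records); fractions default to the strand/coding/age
    composition observed in real spliced-EST screens.
    """

    seed: int = 0
    n_chroms: int = 2
    n_chimeras: int = 50
    n_exonization_decoys: int = 20
    n_plain_ests: int = 30
    n_zero_orientation: int = 5
    n_multi_alignment: int = 5
    n_background_l1: int = 8
    chimeras_per_gene: int = 1
    sense_fraction: float = 0.921
    coding_fraction: float = 0.27
    class_weights: dict = field(
        default_factory=lambda: {
            L1HS: 0.026,
            L1PA2_8: 0.1555,
            ANCIENT_PRIMATE: 0.1555,
            ANCIENT_MAMMALIAN: 0.663,
        }
    )
    consensus_lengths: dict = field(
        default_factory=lambda: {
            L1HS: 6064,
            L1PA2_8: 6100,
            ANCIENT_PRIMATE: 6100,
            ANCIENT_MAMMALIAN: 6000,
        }
    )
    mutation_rate: float = 0.02
    young_tss_range: tuple[int, int] = (150, 600)
    ancient_tss_fraction: tuple[float, float] = (0.80, 0.98)
    fixed_tss_position: Optional[dict] = None  # class -> consensus position
    first_block_len: int = 150
    exon_len: int = 480
    utr_len: int = 900
    motif_site: str = "CCATCT"
    motif_positions: tuple[int, ...] = (12, 447)
    n_reads_per_tss: int = 40
    read_len: int = 36
    pileup_span: int = 200
    n_reads_per_motif_site: int = 200
    chip_library_size: int = 1_000_000
    input_library_size: int = 1_000_000

    def validate(self) -> None:
        for name in (
            "n_chimeras",
            "n_exonization_decoys",
            "n_plain_ests",
            "n_zero_orientation",
            "n_multi_alignment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.n_chimeras > 0 and not self.class_weights:
            raise ValueError("chimeras requested but no L1 class weights given")
        if self.n_multi_alignment > self.n_chimeras:
            raise ValueError("n_multi_alignment cannot exceed n_chimeras")
        lo, hi = self.young_tss_range
        if lo < self.first_block_len:
            raise ValueError("young TSS range must leave room for the first block")
        if self.exon_len < 3 * 141 + 30:
            raise ValueError("exon_len too short to plant a 100+ aa ORF")


@dataclass
class ChimeraTruth:
    id: str
    chrom: str
    gene_id: str
    subfamily_class: str
    subfamily: str
    anchor: tuple  # (chrom, start, end, strand)
    txn_strand: str
    tss_genome: int
    tss_consensus: int
    tss_consensus_pct: float
    sense_to_gene: bool
    coding: bool
    multi_alignment: bool = False


@dataclass
class GroundTruth:
    labels: dict  # id -> label
    chimeras: list  # list of ChimeraTruth
    decoy_ids: list
    supporter_ids: list
    per_gene_counts: dict
    motif_sites: list  # (consensus_id, start0, end0, site)
    tss_sites: list  # (chrom, pos, strand) of planted chimera TSSs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chimeras"] = [asdict(c) if not isinstance(c, dict) else c for c in self.chimeras]
        return d


@dataclass
class SimData:
    config: SimConfig
    transcripts: list
    orientation: dict
    repeats: list
    genes: list
    transcript_seqs: dict
    consensus_seqs: dict
    chip_reads: ReadSet
    input_reads: ReadSet
    consensus_chip_reads: ReadSet
    consensus_input_reads: ReadSet
    pwm_counts: np.ndarray
    pwm_id: str
    chrom_lengths: dict
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write all inputs as plain-text files (BED/TSV/FASTA/JASPAR/JSON)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        lio.write_bed12_transcripts(self.transcripts, out / "ests.bed")
        lio.write_orientation_table(self.orientation, out / "orientation.tsv")
        lio.write_repeats_bed(self.repeats, out / "repeats.bed")
        lio.write_genes_bed12(self.genes, out / "genes.bed")
        lio.write_fasta(self.transcript_seqs, out / "transcripts.fa")
        lio.write_fasta(self.consensus_seqs, out / "consensus.fa")
        lio.write_reads_bed(self.chip_reads, out / "reads_chip.bed")
        lio.write_reads_bed(self.input_reads, out / "reads_input.bed")
        lio.write_reads_bed(self.consensus_chip_reads, out / "reads_consensus_chip.bed")
        lio.write_reads_bed(self.consensus_input_reads, out / "reads_consensus_input.bed")
        _write_jaspar(self.pwm_id, self.pwm_counts, out / "motifs.jaspar")
        meta = {
            "chrom_lengths": self.chrom_lengths,
            "chip_library_size": self.chip_reads.library_size,
            "input_library_size": self.input_reads.library_size,
            "truth": self.truth.to_dict(),
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def _write_jaspar(motif_id: str, counts: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif_id} {motif_id}\n")
        for row, base in zip(counts, "ACGT"):
            cells = " ".join(f"{int(v):>4d}" for v in row)
            fh.write(f"{base}  [ {cells} ]\n")


def _seq_to_str(arr: np.ndarray) -> str:
    return _IDX2BASE[arr].tobytes().decode()


def _str_to_idx(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(arr == 255):
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    out = arr.copy()
    if rate > 0:
        mask = rng.random(len(arr)) < rate
        shift = rng.integers(1, 4, size=len(arr))
        out[mask] = (out[mask] + shift[mask]) % 4
    return out


# ---------------------------------------------------------------------------
# locus builders (all coordinates locus-local until placement)


@dataclass
class _Locus:
    kind: str
    length: int
    payload: dict


def _transcript_pos_to_genome(blocks, txn_strand, t):
    """Map a transcript coordinate to (genome position, complement?)."""
    total = sum(b.width for b in blocks)
    if txn_strand == "-":
        t = total - 1 - t
    for b in blocks:
        if t < b.width:
            return b.start + t, txn_strand == "-"
        t -= b.width
    raise IndexError("transcript position outside blocks")


def _extract_transcript(genome, chrom, blocks, txn_strand) -> np.ndarray:
    parts = [genome[chrom][b.start : b.end] for b in blocks]
    seq = np.concatenate(parts)
    if txn_strand == "-":
        seq = (3 - seq)[::-1]
    return seq


class _Simulator:
    def __init__(self, config: SimConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.cursors = {f"chr{i + 1}": 1200 for i in range(config.n_chroms)}
        self.chrom_order = list(self.cursors)
        self._next_chrom = 0
        self.transcripts: list[SplicedTranscript] = []
        self.orientation: dict[str, int] = {}
        self.repeats: list[RepeatElement] = []
        self.genes: list[GeneModel] = []
        self.labels: dict[str, str] = {}
        self.chimera_truth: list[ChimeraTruth] = []
        self.decoy_ids: list[str] = []
        self.supporter_ids: list[str] = []
        self.per_gene_counts: dict[str, int] = {}
        self.seq_directives: list[tuple[str, int, np.ndarray]] = []
        self.est_counter = 0
        self.gene_counter = 0
        # consensus backbones, with motif sites planted in young-class 5' UTRs
        self.consensus: dict[str, np.ndarray] = {}
        site = _str_to_idx(config.motif_site)
        self.motif_sites: list[tuple[str, int, int, str]] = []
        for cls in SUBFAMILY_CLASSES:
            length = config.consensus_lengths[cls]
            arr = self.rng.integers(0, 4, size=length, dtype=np.uint8)
            if cls in _YOUNG:
                for pos in config.motif_positions:
                    arr[pos : pos + len(site)] = site
                    self.motif_sites.append(
                        (f"{cls}_consensus", pos, pos + len(site), config.motif_site)
                    )
            self.consensus[cls] = arr

    # -- placement ---------------------------------------------------------

    def _place(self, length: int) -> tuple[str, int]:
        chrom = self.chrom_order[self._next_chrom % len(self.chrom_order)]
        self._next_chrom += 1
        offset = self.cursors[chrom]
        self.cursors[chrom] = offset + length + 400
        return chrom, offset

    def _new_est_id(self) -> str:
        self.est_counter += 1
        return f"EST{self.est_counter:05d}"

    def _new_gene_id(self) -> str:
        self.gene_counter += 1
        return f"GENE{self.gene_counter:04d}"

    def _emit_orientation(self, tid: str, txn: str, align: str, zero: bool = False) -> None:
        if zero:
            self.orientation[tid] = 0
        else:
            mag = int(self.rng.integers(1, 4))
            self.orientation[tid] = mag if txn == align else -mag

    # -- locus builders ----------------------------------------------------

    def add_chimera_locus(self, n_ests: int, with_decoy_supporter: bool = False):
        cfg = self.cfg
        classes = list(cfg.class_weights)
        weights = np.array([cfg.class_weights[c] for c in classes], dtype=float)
        cls = classes[int(self.rng.choice(len(classes), p=weights / weights.sum()))]
        cons = self.consensus[cls]
        clen = len(cons)
        if cls in _YOUNG:
            cs, ce = 0, clen
        else:
            cs = int(self.rng.integers(int(0.25 * clen), int(0.45 * clen)))
            ce = clen
        flen = ce - cs
        txn = "+" if self.rng.random() < 0.5 else "-"
        l1_strand = "-" if txn == "+" else "+"
        subfamily = str(self.rng.choice(_SUBFAMILY_NAMES[cls]))
        exon_len = cfg.exon_len

        if txn == "+":
            exon1 = (50, 110)
            l1 = (300, 300 + flen)
            exon2 = (l1[1] + 200, l1[1] + 200 + exon_len)
            length = exon2[1] + 100
        else:
            exon2 = (50, 50 + exon_len)
            l1 = (exon2[1] + 200, exon2[1] + 200 + flen)
            exon1 = (l1[1] + 200, l1[1] + 260)
            length = exon1[1] + 100
        chrom, off = self._place(length)

        def iv(lo_hi, strand="."):
            return GenomicInterval(chrom, off + lo_hi[0], off + lo_hi[1], strand)

        l1_start, l1_end = off + l1[0], off + l1[1]
        anchor = RepeatElement(chrom, l1_start, l1_end, l1_strand, subfamily, "L1")
        self.repeats.append(anchor)
        # L1 footprint sequence: consensus segment (mutated), oriented
        seg = _mutate(self.rng, cons[cs:ce], cfg.mutation_rate)
        if l1_strand == "-":
            seg = (3 - seg)[::-1]
        self.seq_directives.append((chrom, l1_start, seg))

        gene_sense = self.rng.random() < cfg.sense_fraction
        gene_strand = txn if gene_sense else ("-" if txn == "+" else "+")
        exons = sorted([exon1, exon2])
        gene = GeneModel(
            gene_id=self._new_gene_id(),
            chrom=chrom,
            strand=gene_strand,
            exons=tuple(GenomicInterval(chrom, off + a, off + b, gene_strand) for a, b in exons),
        )
        self.genes.append(gene)
        coding = bool(self.rng.random() < cfg.coding_fraction)

        ests = []
        for _ in range(n_ests):
            if cfg.fixed_tss_position and cls in cfg.fixed_tss_position:
                p = int(cfg.fixed_tss_position[cls])
            elif cls in _YOUNG:
                p = int(self.rng.integers(*cfg.young_tss_range))
            else:
                f0, f1 = cfg.ancient_tss_fraction
                p = int(self.rng.integers(int(f0 * clen), int(f1 * clen)))
            if p < cs + cfg.first_block_len:
                p = cs + cfg.first_block_len
            align = "+" if self.rng.random() < 0.5 else "-"
            if txn == "+":
                g = l1_start + (ce - 1 - p)
                block1 = GenomicInterval(chrom, g, g + cfg.first_block_len, align)
                block2 = iv(exon2, align)
                blocks = (block1, block2)
            else:
                g = l1_start + (p - cs)
                block1 = GenomicInterval(chrom, g - cfg.first_block_len + 1, g + 1, align)
                block2 = iv(exon2, align)
                blocks = (block2, block1)
            tid = self._new_est_id()
            t = SplicedTranscript(
                id=tid,
                chrom=chrom,
                align_start=blocks[0].start,
                align_end=blocks[-1].end,
                align_strand=align,
                blocks=blocks,
            )
            self.transcripts.append(t)
            self._emit_orientation(tid, txn, align)
            self.labels[tid] = "exonization_decoy" if with_decoy_supporter else "true_chimera"
            ests.append((tid, t, g, p))
            if with_decoy_supporter:
                self.decoy_ids.append(tid)
            else:
                self.per_gene_counts[gene.gene_id] = (
                    self.per_gene_counts.get(gene.gene_id, 0) + 1
                )
                self.chimera_truth.append(
                    ChimeraTruth(
                        id=tid,
                        chrom=chrom,
                        gene_id=gene.gene_id,
                        subfamily_class=cls,
                        subfamily=subfamily,
                        anchor=(chrom, l1_start, l1_end, l1_strand),
                        txn_strand=txn,
                        tss_genome=g,
                        tss_consensus=p,
                        tss_consensus_pct=100.0 * p / clen,
                        sense_to_gene=gene_sense,
                        coding=coding,
                    )
                )

        if with_decoy_supporter:
            # independent EST with the exon-L1-exon structure over this L1
            sid = self._new_est_id()
            mid = l1_start + flen // 2
            blockB = GenomicInterval(chrom, mid, mid + 120, "+")
            blocks = tuple(sorted([iv(exon1, "+"), blockB, iv(exon2, "+")], key=lambda b: b.start))
            s = SplicedTranscript(
                id=sid,
                chrom=chrom,
                align_start=blocks[0].start,
                align_end=blocks[-1].end,
                align_strand="+",
                blocks=blocks,
            )
            self.transcripts.append(s)
            self._emit_orientation(sid, txn, "+")
            self.labels[sid] = "exonization_support"
            self.supporter_ids.append(sid)

        return ests, coding, cls

    def add_plain_locus(self, zero_orientation: bool = False) -> str:
        cfg = self.cfg
        exon1 = (50, 250)
        exon2 = (700, 1000)
        length = 1200
        chrom, off = self._place(length)
        strand = "+" if self.rng.random() < 0.5 else "-"
        gene = GeneModel(
            gene_id=self._new_gene_id(),
            chrom=chrom,
            strand=strand,
            exons=(
                GenomicInterval(chrom, off + exon1[0], off + exon1[1], strand),
                GenomicInterval(chrom, off + exon2[0], off + exon2[1], strand),
            ),
        )
        self.genes.append(gene)
        tid = self._new_est_id()
        align = "+" if self.rng.random() < 0.5 else "-"
        t = SplicedTranscript(
            id=tid,
            chrom=chrom,
            align_start=gene.exons[0].start,
            align_end=gene.exons[-1].end,
            align_strand=align,
            blocks=tuple(
                GenomicInterval(chrom, e.start, e.end, align) for e in gene.exons
            ),
        )
        self.transcripts.append(t)
        self._emit_orientation(tid, strand, align, zero=zero_orientation)
        self.labels[tid] = "zero_orientation" if zero_orientation else "plain_gene_est"
        return tid

    def add_secondary_alignment(self, tid: str) -> None:
        """A second, barren alignment of an existing id (multi-alignment flag)."""
        length = 600
        chrom, off = self._place(length)
        blocks = (
            GenomicInterval(chrom, off + 50, off + 110, "+"),
            GenomicInterval(chrom, off + 300, off + 360, "+"),
        )
        t = SplicedTranscript(
            id=tid,
            chrom=chrom,
            align_start=blocks[0].start,
            align_end=blocks[-1].end,
            align_strand="+",
            blocks=blocks,
        )
        self.transcripts.append(t)

    def add_background_l1(self) -> None:
        cfg = self.cfg
        cls = ANCIENT_MAMMALIAN
        cons = self.consensus[cls]
        cs = int(self.rng.integers(int(0.3 * len(cons)), int(0.6 * len(cons))))
        flen = len(cons) - cs
        chrom, off = self._place(flen + 200)
        strand = "+" if self.rng.random() < 0.5 else "-"
        subfamily = str(self.rng.choice(_SUBFAMILY_NAMES[cls]))
        self.repeats.append(
            RepeatElement(chrom, off + 100, off + 100 + flen, strand, subfamily, "L1")
        )
        seg = _mutate(self.rng, cons[cs:], cfg.mutation_rate)
        if strand == "-":
            seg = (3 - seg)[::-1]
        self.seq_directives.append((chrom, off + 100, seg))

    # -- genome materialization and sequence-level planting ------------------

    def build_genome(self) -> dict[str, np.ndarray]:
        genome = {}
        for chrom in self.chrom_order:
            length = self.cursors[chrom] + 1200
            genome[chrom] = self.rng.integers(0, 4, size=length, dtype=np.uint8)
        for chrom, start, seg in self.seq_directives:
            genome[chrom][start : start + len(seg)] = seg
        self.chrom_lengths = {c: len(a) for c, a in genome.items()}
        return genome

    def _write_transcript_pos(self, genome, t: SplicedTranscript, txn: str, tpos: int, base_idx: int):
        gpos, comp = _transcript_pos_to_genome(t.blocks, txn, tpos)
        genome[t.chrom][gpos] = (3 - base_idx) if comp else base_idx

    def plant_orf(self, genome, t: SplicedTranscript, txn: str) -> None:
        cfg = self.cfg
        aa = int(self.rng.integers(100, 141))
        codons = ["ATG"] + [
            _NON_STOP_CODONS[int(i)]
            for i in self.rng.integers(0, len(_NON_STOP_CODONS), size=aa - 1)
        ] + ["TAA"]
        orf = _str_to_idx("".join(codons))
        t0 = cfg.first_block_len + 9
        for j, b in enumerate(orf):
            self._write_transcript_pos(genome, t, txn, t0 + j, int(b))

    def scrub_long_orfs(self, genome, locus_ests, protected: int) -> None:
        """Disrupt every >=100 aa ORF by writing a stop codon outside the
        protected 5' (consensus-derived) region; iterate to a fixpoint over
        all records sharing the locus."""
        stop = _str_to_idx("TAA")
        for _ in range(60):
            dirty = False
            for t, txn in locus_ests:
                seq = _seq_to_str(_extract_transcript(genome, t.chrom, t.blocks, txn))
                for orf in find_orfs(seq):
                    if orf.peptide_length_aa < 100:
                        continue
                    c = orf.start_nt
                    if c < protected:
                        c += 3 * math.ceil((protected - c) / 3)
                    if c + 3 > orf.start_nt + 3 * orf.peptide_length_aa:
                        continue  # cannot scrub without touching protected 5' end
                    for j in range(3):
                        self._write_transcript_pos(genome, t, txn, c + j, int(stop[j]))
                    dirty = True
            if not dirty:
                return
        raise RuntimeError("ORF scrubbing failed to converge")

    # -- reads --------------------------------------------------------------

    def make_genomic_reads(self, tss_sites) -> tuple[ReadSet, ReadSet]:
        cfg = self.cfg
        chip = []
        for chrom, pos, strand in tss_sites:
            offsets = self.rng.integers(0, cfg.pileup_span - cfg.read_len, size=cfg.n_reads_per_tss)
            for d in offsets:
                if strand == "+":
                    s = pos + int(d)
                else:
                    s = pos - int(d) - cfg.read_len + 1
                chip.append((chrom, s, s + cfg.read_len, strand))
        inputs = []
        for chrom in self.chrom_order:
            n = self.chrom_lengths[chrom] // 400
            starts = self.rng.integers(0, self.chrom_lengths[chrom] - cfg.read_len, size=n)
            strands = self.rng.random(n) < 0.5
            for s, plus in zip(starts, strands):
                inputs.append((chrom, int(s), int(s) + cfg.read_len, "+" if plus else "-"))
        return (
            ReadSet(chip, cfg.chip_library_size),
            ReadSet(inputs, cfg.input_library_size),
        )

    def make_consensus_reads(self) -> tuple[ReadSet, ReadSet]:
        cfg = self.cfg
        ref = f"{L1HS}_consensus"
        clen = cfg.consensus_lengths[L1HS]
        chip = []
        for pos in cfg.motif_positions:
            center = pos + len(cfg.motif_site) // 2
            jitter = self.rng.integers(-20, 21, size=cfg.n_reads_per_motif_site)
            for d in jitter:
                s = max(0, min(clen - cfg.read_len, center - cfg.read_len // 2 + int(d)))
                chip.append((ref, s, s + cfg.read_len, "+"))
        starts = self.rng.integers(0, clen - cfg.read_len, size=300)
        inputs = [(ref, int(s), int(s) + cfg.read_len, "+") for s in starts]
        return (
            ReadSet(chip, cfg.chip_library_size),
            ReadSet(inputs, cfg.input_library_size),
        )


def simulate(config: SimConfig) -> SimData:
    """Generate a full synthetic cohort with ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    outputs from :meth:`SimData.write`.
    """
    sim = _Simulator(config)
    cfg = config

    # chimera gene loci (grouped when chimeras_per_gene > 1)
    chimera_units: list[tuple] = []
    remaining = cfg.n_chimeras
    while remaining > 0:
        k = min(cfg.chimeras_per_gene, remaining)
        ests, coding, cls = sim.add_chimera_locus(k)
        chimera_units.append((ests, coding))
        remaining -= k
    for _ in range(cfg.n_exonization_decoys):
        sim.add_chimera_locus(1, with_decoy_supporter=True)
    for _ in range(cfg.n_plain_ests):
        sim.add_plain_locus()
    for _ in range(cfg.n_zero_orientation):
        sim.add_plain_locus(zero_orientation=True)
    for _ in range(cfg.n_background_l1):
        sim.add_background_l1()

    # secondary alignments for the first n_multi_alignment chimera ids
    multi_ids = [ct.id for ct in sim.chimera_truth[: cfg.n_multi_alignment]]
    for tid in multi_ids:
        sim.add_secondary_alignment(tid)
    for ct in sim.chimera_truth:
        if ct.id in multi_ids:
            ct.multi_alignment = True
    n_by_id: dict[str, int] = {}
    for t in sim.transcripts:
        n_by_id[t.id] = n_by_id.get(t.id, 0) + 1
    sim.transcripts = [
        SplicedTranscript(
            id=t.id,
            chrom=t.chrom,
            align_start=t.align_start,
            align_end=t.align_end,
            align_strand=t.align_strand,
            blocks=t.blocks,
            intron_orientation=sim.orientation.get(t.id, 0),
            n_alignments=n_by_id[t.id],
        )
        for t in sim.transcripts
    ]

    genome = sim.build_genome()

    # plant / scrub coding ORFs on chimera transcripts (shared per locus)
    by_id = {}
    for t in sim.transcripts:
        by_id.setdefault(t.id, t)
    truth_by_id = {ct.id: ct for ct in sim.chimera_truth}
    for ests, coding in chimera_units:
        locus = [(by_id[tid], truth_by_id[tid].txn_strand) for tid, *_ in ests]
        if coding:
            sim.plant_orf(genome, *locus[0])
        else:
            sim.scrub_long_orfs(genome, locus, cfg.first_block_len)

    # transcript sequences (transcription orientation) for all records
    txn_of = {}
    for t in sim.transcripts:
        if t.id in txn_of:
            continue  # keep the primary alignment's orientation
        o = sim.orientation.get(t.id, 0)
        if o > 0:
            txn_of[t.id] = t.align_strand
        elif o < 0:
            txn_of[t.id] = "-" if t.align_strand == "+" else "+"
    transcript_seqs = {}
    for t in sim.transcripts:
        if t.id in transcript_seqs or t.id not in txn_of:
            continue  # secondary alignments and zero-orientation records: primary/none
        transcript_seqs[t.id] = _seq_to_str(
            _extract_transcript(genome, t.chrom, by_id[t.id].blocks, txn_of[t.id])
        )

    tss_sites = [(ct.chrom, ct.tss_genome, ct.txn_strand) for ct in sim.chimera_truth]
    chip, inputs = sim.make_genomic_reads(tss_sites)
    cons_chip, cons_input = sim.make_consensus_reads()

    site = cfg.motif_site
    w = len(site)
    pwm_counts = np.zeros((4, w))
    for j, b in enumerate(site):
        pwm_counts["ACGT".index(b), j] = 100

    truth = GroundTruth(
        labels=dict(sim.labels),
        chimeras=list(sim.chimera_truth),
        decoy_ids=list(sim.decoy_ids),
        supporter_ids=list(sim.supporter_ids),
        per_gene_counts=dict(sim.per_gene_counts),
        motif_sites=list(sim.motif_sites),
        tss_sites=tss_sites,
    )
    consensus_seqs = {
        f"{cls}_consensus": _seq_to_str(arr) for cls, arr in sim.consensus.items()
    }
    return SimData(
        config=config,
        transcripts=sim.transcripts,
        orientation=dict(sim.orientation),
        repeats=sim.repeats,
        genes=sim.genes,
        transcript_seqs=transcript_seqs,
        consensus_seqs=consensus_seqs,
        chip_reads=chip,
        input_reads=inputs,
        consensus_chip_reads=cons_chip,
        consensus_input_reads=cons_input,
        pwm_counts=pwm_counts,
        pwm_id="YY1SYN1",
        chrom_lengths=dict(sim.chrom_lengths),
        truth=truth,
    )


def simulate_transcript_cohort(
    n: int, coding_fraction: float, seed: int = 0, length: int = 600
) -> tuple[dict[str, str], dict[str, bool]]:
    """A pure sequence cohort with guaranteed per-record coding labels.

    Coding records carry a planted ATG-initiated ORF of 100-140 aa; every
    other >=100 aa ORF (planted records included, outside the planted one)
    is disrupted so non-coding records are truly non-coding.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    labels: dict[str, bool] = {}
    n_coding = int(round(n * coding_fraction))
    for i in range(n):
        coding = i < n_coding
        arr = rng.integers(0, 4, size=length, dtype=np.uint8)
        if coding:
            aa = int(rng.integers(100, 141))
            codons = ["ATG"] + [
                _NON_STOP_CODONS[int(k)]
                for k in rng.integers(0, len(_NON_STOP_CODONS), size=aa - 1)
            ] + ["TAA"]
            orf = _str_to_idx("".join(codons))
            start = int(rng.integers(0, length - len(orf)))
            arr[start : start + len(orf)] = orf
        else:
            # scrub chance long ORFs
            for _ in range(30):
                seq = _seq_to_str(arr)
                long = [o for o in find_orfs(seq) if o.peptide_length_aa >= 100]
                if not long:
                    break
                for o in long:
                    c = o.start_nt + 3 * (o.peptide_length_aa // 2)
                    arr[c : c + 3] = _str_to_idx("TAA")
        seqs[f"T{i:05d}"] = _seq_to_str(arr)
        labels[f"T{i:05d}"] = coding
    # shuffle ids? keep deterministic insertion order; label dict carries truth
    return seqs, labels


# ---------------------------------------------------------------------------
# hand-written micro-fixtures


def make_fixture(name: str) -> dict:
    """Tiny hand-constructed cases for the screen's edge rules.

    Known names: ``exonization_decoy``, ``boundary_tss``, ``overlapping_l1``,
    ``zero_orientation``.  Each returns transcripts/repeats/genes plus the
    expected outcome.
    """
    chrom = "chrT"

    def t(tid, blocks, align="+", orient=1, chrom=chrom):
        ivs = tuple(GenomicInterval(chrom, a, b, align) for a, b in blocks)
        return SplicedTranscript(
            id=tid,
            chrom=chrom,
            align_start=ivs[0].start,
            align_end=ivs[-1].end,
            align_strand=align,
            blocks=ivs,
            intron_orientation=orient,
        )

    gene = GeneModel(
        gene_id="G1",
        chrom=chrom,
        strand="+",
        exons=(
            GenomicInterval(chrom, 100, 200, "+"),
            GenomicInterval(chrom, 3000, 3400, "+"),
        ),
    )
    l1 = RepeatElement(chrom, 500, 2500, "-", "L1HS", "L1")

    if name == "exonization_decoy":
        candidate = t("CAND", [(1000, 1150), (3000, 3400)])  # TSS 1000 in L1, + txn
        supporter = t("SUPP", [(100, 200), (1400, 1500), (3000, 3400)])
        return {
            "transcripts": [candidate, supporter],
            "repeats": [l1],
            "genes": [gene],
            "expect": {"accepted": [], "removed": ["CAND"]},
        }
    if name == "boundary_tss":
        inside = t("IN", [(2499, 2600), (3000, 3400)])  # TSS 2499 = last base of L1
        outside = t("OUT", [(2500, 2600), (3000, 3400)])  # TSS 2500 = one past the end
        return {
            "transcripts": [inside, outside],
            "repeats": [l1],
            "genes": [gene],
            "expect": {"accepted": ["IN"], "removed": []},
        }
    if name == "overlapping_l1":
        l1_anti = RepeatElement(chrom, 500, 2500, "-", "L1PA4", "L1")
        l1_sense = RepeatElement(chrom, 900, 2600, "+", "L1M5", "L1")
        l1_small = RepeatElement(chrom, 950, 1100, "-", "L1HS", "L1")
        cand = t("OVL", [(1000, 1150), (3000, 3400)])  # TSS 1000 inside all three
        return {
            "transcripts": [cand],
            "repeats": [l1_anti, l1_sense, l1_small],
            "genes": [gene],
            # both antisense L1s match; the TSS block [1000,1150) overlaps the
            # big one by 150 bp and the small one by 100 bp -> big one anchors
            "expect": {"accepted": ["OVL"], "anchor_subfamily": "L1PA4"},
        }
    if name == "zero_orientation":
        rec = t("ZERO", [(1000, 1150), (3000, 3400)], orient=0)
        return {
            "transcripts": [rec],
            "repeats": [l1],
            "genes": [gene],
            "expect": {"accepted": [], "dropped_zero_orientation": 1},
        }
    raise KeyError(f"unknown fixture {name!r}")
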