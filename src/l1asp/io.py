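"""Readers and writers for the plain-text formats the pipeline consumes.

Dialects:

* spliced transcripts: BED12 (blockCount/blockSizes/blockStarts, comma
  separated, trailing comma tolerated); the strand column is the *alignment*
  strand.
* orientation table: two tab-separated columns, record id -> signed integer
  (the ``intronOrientation`` semantic).
* repeats: BED6 with two extra columns — chrom, start, end, subfamily,
  score, strand, family (extra columns beyond 7 are ignored).
* genes: BED12, one row per gene, blocks = exons.
* read alignments: BED6 (name and score ignored; strand kept).
* sequences: FASTA via Bio.SeqIO.
* motifs: JASPAR count-matrix text via Bio.motifs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    SplicedTranscript,
)
from .signals import ReadSet


def _split_csv_ints(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def _parse_bed12_row(fields: Sequence[str]) -> tuple[str, str, int, int, str, list[GenomicInterval]]:
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    n_blocks = int(fields[9])
    sizes = _split_csv_ints(fields[10])
    offsets = _split_csv_ints(fields[11])
    if not (len(sizes) == len(offsets) == n_blocks):
        raise ValueError(f"{name}: blockCount disagrees with blockSizes/blockStarts")
    blocks = [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    ]
    return name, chrom, start, end, strand, blocks


def read_bed12_transcripts(path: str | Path) -> list[SplicedTranscript]:
    """Read spliced alignments from BED12.

    ``n_alignments`` is set per record from the number of rows sharing the
    same name (multi-alignment records appear once per alignment).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"BED12 expected, got {len(fields)} columns")
            rows.append(_parse_bed12_row(fields))
    counts = Counter(name for name, *_ in rows)
    out = []
    for name, chrom, start, end, strand, blocks in rows:
        out.append(
            SplicedTranscript(
                id=name,
                chrom=chrom,
                align_start=start,
                align_end=end,
                align_strand=strand,
                blocks=tuple(blocks),
                n_alignments=counts[name],
            )
        )
    return out


def write_bed12_transcripts(transcripts: Iterable[SplicedTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(b.width) for b in t.blocks)
            offsets = ",".join(str(b.start - t.align_start) for b in t.blocks)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.align_start),
                        str(t.align_end),
                        t.id,
                        "0",
                        t.align_strand,
                        str(t.align_start),
                        str(t.align_end),
                        "0",
                        str(len(t.blocks)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_orientation_table(path: str | Path) -> dict[str, int]:
    """Read the id -> intron-orientation integer table (TSV)."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")[:2]
            table[name] = int(value)
    return table


def write_orientation_table(table: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in table:
            fh.write(f"{name}\t{table[name]}\n")


def apply_orientation(
    transcripts: Iterable[SplicedTranscript], table: dict[str, int]
) -> list[SplicedTranscript]:
    """Attach intron-orientation integers by record id (missing id -> 0)."""
    return [replace(t, intron_orientation=table.get(t.id, 0)) for t in transcripts]


def read_repeats_bed(path: str | Path) -> list[RepeatElement]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError("repeat BED needs 7 columns (BED6 + family)")
            out.append(
                RepeatElement(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    subfamily=f[3],
                    strand=f[5],
                    family=f[6],
                )
            )
    return out


def write_repeats_bed(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.subfamily}\t0\t{r.strand}\t{r.family}\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            name, chrom, _start, _end, strand, blocks = _parse_bed12_row(fields)
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=tuple(blocks)))
    return genes


def write_genes_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = g.exons[0].start
            end = g.exons[-1].end
            sizes = ",".join(str(e.width) for e in g.exons)
            offsets = ",".join(str(e.start - start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start),
                        str(end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_reads_bed(path: str | Path, library_size: int) -> ReadSet:
    """Read BED6 alignment records into a :class:`ReadSet`.

    ``library_size`` (the total mapped reads of the library) is supplied by
    the caller; it cannot be inferred from a regional slice of alignments.
    """
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            reads.append((f[0], int(f[1]), int(f[2]), strand))
    return ReadSet(reads=reads, library_size=library_size)


def write_reads_bed(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (ref, start, end, strand) in enumerate(readset.reads):
            fh.write(f"{ref}\t{start}\t{end}\tread{i}\t0\t{strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar(path: str | Path):
    """Read JASPAR count matrices; returns a list of Bio.motifs motif objects."""
    with open(path) as fh:
        return list(bio_motifs.parse(fh, "jaspar"))
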