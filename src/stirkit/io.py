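"""Readers and writers for the plain-text genomic formats the pipeline uses:
GTF, BED6/BED12, bedGraph, FASTA (via pyfaidx) and TSV tables."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

from .annotation_core import GeneModel, LongRead, Region, TranscriptRecord

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse exon features of a GTF into per-transcript records.

    Transcripts are keyed by the ``transcript_id`` attribute and assigned to
    their ``gene_id``.  GTF coordinates (1-based closed) are converted to
    0-based half-open.
    """
    tx: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            key = attrs.get("transcript_id") or attrs["gene_id"]
            rec = tx.setdefault(key, (attrs["gene_id"], f[0], f[6], []))
            rec[3].append((int(f[3]) - 1, int(f[4])))
    out: list[TranscriptRecord] = []
    for gene_id, chrom, strand, exons in tx.values():
        out.append((gene_id, chrom, strand, sorted(exons)))
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "stirkit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for i, exons in enumerate(g.transcripts or [[(g.start, g.end)]]):
                tid = f"{g.gene_id}.t{i + 1}"
                for s, e in exons:
                    fh.write(
                        "\t".join(
                            [
                                g.chrom, source, "exon", str(s + 1), str(e), ".",
                                g.strand, ".",
                                f'gene_id "{g.gene_id}"; transcript_id "{tid}";',
                            ]
                        )
                        + "\n"
                    )


def read_bed12_transcripts(path: str | Path) -> list[TranscriptRecord]:
    """BED12 -> transcript records; the name column is the gene_id."""
    out: list[TranscriptRecord] = []
    for f in _iter_tsv(path):
        start = int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        out.append((f[3], f[0], f[5], sorted(exons)))
    return out


def read_bed12_reads(path: str | Path) -> list[LongRead]:
    """BED12 -> long-read alignments with aligned blocks."""
    reads: list[LongRead] = []
    for f in _iter_tsv(path):
        start = int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        reads.append(
            LongRead(
                name=f[3], chrom=f[0], start=start, end=int(f[2]),
                strand=f[5], blocks=sorted(blocks),
            )
        )
    return reads


def write_bed12_reads(reads: Iterable[LongRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - r.start) for s, _ in r.blocks)
            fh.write(
                "\t".join(
                    [
                        r.chrom, str(r.start), str(r.end), r.name, "0", r.strand,
                        str(r.start), str(r.end), "0", str(len(r.blocks)),
                        sizes, offsets,
                    ]
                )
                + "\n"
            )


def _iter_tsv(path: str | Path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith(("#", "track")):
                yield line.split("\t")


def write_bed6(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                "\t".join(
                    [r.chrom, str(r.start), str(r.end), r.name, "0", r.strand]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Generic BED3+ into a DataFrame (chrom, start, end, then name/score/...)."""
    rows = list(_iter_tsv(path))
    ncol = max(len(r) for r in rows) if rows else 3
    names = ["chrom", "start", "end", "name", "score", "strand", "class"][:ncol]
    df = pd.DataFrame(rows, columns=names + [f"c{i}" for i in range(ncol - len(names))])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def extract_region_sequences(
    regions: Sequence[Region], fasta_path: str | Path
) -> dict[str, str]:
    """Region sequences, 5'->3' on the transcribed strand (minus-strand
    regions are reverse-complemented)."""
    fa = Fasta(str(fasta_path))
    out: dict[str, str] = {}
    for r in regions:
        rec = fa[r.chrom][r.start:r.end]
        seq = str(rec.reverse.complement if r.strand == "-" else rec)
        out[r.name] = seq.upper()
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with a gene_id column and one TPM column per sample."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")
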