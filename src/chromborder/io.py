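"""Readers and writers for the plain-text formats the pipeline consumes.

BED (3-6 columns) for intervals and nucleosomes, BED6 for tag files (score
column = read length), bedGraph for coverage vectors, TSV for matrices
(first column = row id, header = strain/sample ids), FASTA for sequence.
1-based formats do not appear here; all BED-family coordinates are 0-based
half-open on both sides of the boundary.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, NucleosomeRecord, Tag

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _read_bed_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}, skip_blank_lines=True
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = _BED_COLS[: df.shape[1]]
    return df


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals."""
    df = _read_bed_frame(path)
    has_name = "name" in df.columns
    has_strand = "strand" in df.columns
    out = []
    for row in df.itertuples(index=False):
        name = str(row.name) if has_name and not pd.isna(row.name) else None
        strand = str(row.strand) if has_strand and row.strand in ("+", "-") else "."
        out.append(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end), strand, name)
        )
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6 (name '.', score 0 unless given)."""
    scores_list = None if scores is None else list(scores)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, iv in enumerate(intervals):
            score = scores_list[i] if scores_list is not None else 0
            w.writerow([iv.chrom, iv.start, iv.end, iv.id or ".", score, iv.strand])


def read_nucleosomes(path: str | Path) -> list[NucleosomeRecord]:
    """Read nucleosomes from BED; the 5th (score) column is the occupancy score."""
    df = _read_bed_frame(path)
    out = []
    for row in df.itertuples(index=False):
        score = float(row.score) if "score" in df.columns else 0.0
        name = str(row.name) if "name" in df.columns and not pd.isna(row.name) else None
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end), ".", name)
        out.append(NucleosomeRecord(iv, score))
    return out


def write_nucleosomes(nucs: Iterable[NucleosomeRecord], path: str | Path) -> None:
    nucs = list(nucs)
    write_bed([n.interval for n in nucs], path, scores=[n.occupancy_score for n in nucs])


def read_tags(path: str | Path) -> list[Tag]:
    """Read a BED6 tag file: score column = read length, 6th column = strand."""
    df = _read_bed_frame(path)
    if "strand" not in df.columns:
        raise ValueError(f"{path}: tag files must be BED6 (strand column required)")
    out = []
    for row in df.itertuples(index=False):
        length = int(row.score)
        strand = str(row.strand) if row.strand in ("+", "-") else "+"
        out.append(Tag(str(row.chrom), int(row.start), strand, length))
    return out


def write_tags(tags: Iterable[Tag], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for t in tags:
            w.writerow(
                [t.chrom, t.position, t.position + t.length, ".", t.length, t.strand]
            )


def write_bedgraph(
    chrom: str, start: int, values: Sequence[float] | np.ndarray, path: str | Path
) -> None:
    """Write a per-base vector as bedGraph, merging runs of equal value."""
    vals = np.asarray(values)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if vals.size == 0:
            return
        run_start = 0
        for i in range(1, vals.size + 1):
            if i == vals.size or vals[i] != vals[run_start]:
                w.writerow([chrom, start + run_start, start + i, vals[run_start]])
                run_start = i


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: first column = row ids, header = column ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
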