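"""Coordinate conventions and primitive genomic types.

Everything downstream — peak refinement, meta-profiles, homolog mapping, the
synthetic study generator — is built on three small value types defined here:

* :class:`GenomicInterval` — a half-open genomic span. All coordinates are
  0-based, half-open (BED convention); 1-based inputs are converted at I/O
  boundaries, never here.
* :class:`Tag` — one mapped sequencing read (leftmost base, strand, length).
  When a read must be reduced to a single base pair (DNase cut sites), the
  convention is the read's 5' end: the leftmost mapped base on the plus
  strand, the rightmost on the minus strand.
* :class:`NucleosomeRecord` — a positioned nucleosome with an occupancy
  score (log-normalized in vitro score, or an in vivo read count).

Plus the shared primitives: fixed-length read extension, nearest-feature
queries with a deterministic tie-break, and per-base coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded). ``id`` is an
    optional label carried through file round-trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, integer-floored."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + delta, self.end + delta, self.strand, self.id
        )


@dataclass
class Tag:
    """One mapped sequencing read.

    ``position`` is the 0-based leftmost mapped base regardless of strand;
    ``length`` is the mapped read length in bp.
    """

    chrom: str
    position: int
    strand: str = "+"
    length: int = 36

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def cut_site(self) -> int:
        """Single-bp point location of the read: its 5' end.

        Leftmost base for plus/unstranded reads, rightmost for minus-strand
        reads. This is the DNase cut-site convention used for DHS tags.
        """
        if self.strand == "-":
            return self.position + self.length - 1
        return self.position

    @property
    def footprint(self) -> GenomicInterval:
        """The full mapped span ``[position, position + length)``."""
        return GenomicInterval(self.chrom, self.position, self.position + self.length)


@dataclass
class NucleosomeRecord:
    """A positioned nucleosome with an occupancy score.

    The score is a log-normalized in vitro occupancy (positive values mean
    sequence-encoded enrichment relative to the genome average) or an in vivo
    read count, depending on the source assay.
    """

    interval: GenomicInterval
    occupancy_score: float = 0.0

    @property
    def dyad(self) -> int:
        """Dyad position: interval midpoint, integer-floored."""
        return self.interval.center


def extend_reads(tags: Iterable[Tag], target_length: int) -> list[GenomicInterval]:
    """Extend (or truncate) reads to a fixed length from their 5' ends.

    A plus/unstranded tag at leftmost base ``p`` becomes ``[p, p + T)``; a
    minus-strand tag with leftmost base ``p`` and length ``L`` becomes
    ``[p + L - T, p + L)``. Coordinates are clipped at zero, so clipped
    intervals may be shorter than ``T``. ``T`` smaller than the read length
    truncates the read to ``T`` bases from its 5' end.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    out: list[GenomicInterval] = []
    for tag in tags:
        if tag.strand == "-":
            end = tag.position + tag.length
            start = max(0, end - target_length)
        else:
            start = tag.position
            end = start + target_length
        out.append(GenomicInterval(tag.chrom, start, end, tag.strand))
    return out


def nearest_feature(
    query: int,
    features: Sequence[int] | np.ndarray,
    max_dist: int | None = None,
) -> tuple[int, int] | None:
    """Nearest feature position to ``query`` and its signed distance.

    Returns ``(position, position - query)`` for the feature minimizing the
    absolute distance, or ``None`` if there are no features or the minimum
    exceeds ``max_dist``. Ties break toward the smaller coordinate so output
    is deterministic.
    """
    feats = np.asarray(features, dtype=np.int64)
    if feats.size == 0:
        return None
    feats = np.sort(feats)
    idx = int(np.searchsorted(feats, query))
    best: int | None = None
    if idx > 0:
        best = int(feats[idx - 1])
    if idx < feats.size:
        right = int(feats[idx])
        if best is None or abs(right - query) < abs(best - query):
            best = right
    assert best is not None
    dist = best - query
    if max_dist is not None and abs(dist) > max_dist:
        return None
    return best, dist


def coverage(
    intervals: Iterable[GenomicInterval], window: GenomicInterval
) -> np.ndarray:
    """Per-base interval count across ``window``.

    ``out[b]`` is the number of intervals containing base ``window.start + b``;
    intervals on other chromosomes are ignored.
    """
    out = np.zeros(window.width, dtype=np.int64)
    for iv in intervals:
        if iv.chrom != window.chrom:
            continue
        lo = max(iv.start, window.start) - window.start
        hi = min(iv.end, window.end) - window.start
        if lo < hi:
            out[lo:hi] += 1
    return out


def intervals_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Group intervals by chromosome, each group sorted by start."""
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault(iv.chrom, []).append(iv)
    for ivs in groups.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return groups
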