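"""Peak-editing procedures for open-chromatin and TF ChIP peaks.

Three operations:

* :func:`refine_peak_ends` — adjust open-chromatin peak ends outward until
  the number of DNase cut sites left outside each boundary does not exceed
  the genome-wide expected (average) outside count.
* :func:`filter_tf_peaks` — locate each TF peak's summit (the base covered
  by the most ChIP read footprints) and keep only peaks where at least a
  fraction ``min_frac`` of the peak's reads cover that summit, i.e. peaks
  likely to contain a single focused binding site.
* :func:`nucleosome_containing_fraction` — census of open-chromatin regions
  whose span contains at least one nucleosome dyad.

DHS tags are counted as single-bp cut sites (read 5' ends); ChIP tags are
counted as full read footprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GenomicInterval, NucleosomeRecord, Tag, coverage


@dataclass
class RefinedPeak:
    """One peak before/after DHS-based end refinement.

    ``satisfied`` flags per side record whether an extension within
    ``max_extend`` brought the outside count at or below the expected count.
    Refinement is extension-only: ``refined.start <= original.start`` and
    ``refined.end >= original.end``.
    """

    original: GenomicInterval
    refined: GenomicInterval
    expected_outside: float
    left_extension: int
    right_extension: int
    left_outside_count: int
    right_outside_count: int
    left_satisfied: bool
    right_satisfied: bool


@dataclass
class TfPeak:
    """A TF ChIP peak with its summit and summit tag-coverage fraction."""

    interval: GenomicInterval
    summit: int
    tags_total: int
    tags_on_summit: int
    kept: bool

    @property
    def summit_fraction(self) -> float:
        return self.tags_on_summit / self.tags_total


def _cut_sites_by_chrom(tags: Iterable[Tag]) -> dict[str, np.ndarray]:
    sites: dict[str, list[int]] = {}
    for t in tags:
        sites.setdefault(t.chrom, []).append(t.cut_site)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in sites.items()}


def _count_in(points: np.ndarray, lo, hi) -> np.ndarray | int:
    """Count points in half-open [lo, hi); lo/hi may be arrays."""
    return np.searchsorted(points, hi, side="left") - np.searchsorted(
        points, lo, side="left"
    )


def refine_peak_ends(
    peaks: Sequence[GenomicInterval],
    dhs_tags: Iterable[Tag],
    flank_w: int = 200,
    max_extend: int = 500,
) -> list[RefinedPeak]:
    """Extend peak ends outward until outside DHS counts drop to the average.

    The expected count ``E`` is the mean, over all peaks and both sides, of
    DHS cut sites in the outside window of width ``flank_w`` adjacent to the
    original boundary. Each side is then extended outward by the minimal
    ``delta in [0, max_extend]`` such that the cut-site count in the window
    of width ``flank_w`` just outside the new boundary is <= ``E``. If no
    such ``delta`` exists, the side is clipped at ``max_extend`` with
    ``satisfied=False``. The left end never extends below coordinate 0.
    """
    if flank_w <= 0:
        raise ValueError("flank_w must be positive")
    if max_extend < 0:
        raise ValueError("max_extend must be >= 0")
    points = _cut_sites_by_chrom(dhs_tags)
    empty = np.empty(0, dtype=np.int64)

    side_counts = []
    for pk in peaks:
        pts = points.get(pk.chrom, empty)
        side_counts.append(int(_count_in(pts, pk.start - flank_w, pk.start)))
        side_counts.append(int(_count_in(pts, pk.end, pk.end + flank_w)))
    expected = float(np.mean(side_counts)) if side_counts else 0.0

    out: list[RefinedPeak] = []
    deltas = np.arange(0, max_extend + 1, dtype=np.int64)
    for pk in peaks:
        pts = points.get(pk.chrom, empty)
        # left: new boundary start - delta; outside window [b - flank_w, b)
        bounds = pk.start - deltas
        counts = _count_in(pts, bounds - flank_w, bounds)
        ok = np.nonzero(counts <= expected)[0]
        if ok.size:
            dl, left_ok = int(deltas[ok[0]]), True
        else:
            dl, left_ok = max_extend, False
        dl = min(dl, pk.start)  # never extend past coordinate 0
        left_count = int(_count_in(pts, pk.start - dl - flank_w, pk.start - dl))

        # right: new boundary end + delta; outside window [b, b + flank_w)
        bounds = pk.end + deltas
        counts = _count_in(pts, bounds, bounds + flank_w)
        ok = np.nonzero(counts <= expected)[0]
        if ok.size:
            dr, right_ok = int(deltas[ok[0]]), True
        else:
            dr, right_ok = max_extend, False
        right_count = int(_count_in(pts, pk.end + dr, pk.end + dr + flank_w))

        refined = GenomicInterval(
            pk.chrom, pk.start - dl, pk.end + dr, pk.strand, pk.id
        )
        out.append(
            RefinedPeak(
                original=pk,
                refined=refined,
                expected_outside=expected,
                left_extension=dl,
                right_extension=dr,
                left_outside_count=left_count,
                right_outside_count=right_count,
                left_satisfied=left_ok,
                right_satisfied=right_ok,
            )
        )
    return out


def filter_tf_peaks(
    peaks: Sequence[GenomicInterval],
    chip_tags: Iterable[Tag],
    min_frac: float = 0.8,
) -> list[TfPeak]:
    """Summit-find TF peaks and keep those with focused tag coverage.

    Tags are assigned to a peak when their full footprint overlaps it. The
    summit is the base inside the peak with maximal footprint coverage
    (leftmost on ties); a peak is kept iff the fraction of its tags whose
    footprint covers the summit is >= ``min_frac``. Peaks with zero
    overlapping tags are discarded from the output entirely.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    footprints: dict[str, list[GenomicInterval]] = {}
    for t in chip_tags:
        footprints.setdefault(t.chrom, []).append(t.footprint)

    out: list[TfPeak] = []
    for pk in peaks:
        fps = [fp for fp in footprints.get(pk.chrom, []) if fp.overlaps(pk)]
        if not fps:
            continue
        cov = coverage(fps, pk)
        summit = pk.start + int(np.argmax(cov))  # argmax is leftmost on ties
        on_summit = sum(1 for fp in fps if fp.start <= summit < fp.end)
        kept = on_summit / len(fps) >= min_frac
        out.append(TfPeak(pk, summit, len(fps), on_summit, kept))
    return out


def nucleosome_containing_fraction(
    regions: Sequence[GenomicInterval],
    nucleosomes: Iterable[NucleosomeRecord | GenomicInterval],
) -> tuple[float, list[bool]]:
    """Fraction of regions containing at least one nucleosome dyad.

    A region contains a nucleosome iff the nucleosome's dyad (interval
    midpoint, integer-floored) lies within ``[start, end)``. Returns the
    fraction and the per-region containment flags.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    dyads: dict[str, list[int]] = {}
    for n in nucleosomes:
        iv = n.interval if isinstance(n, NucleosomeRecord) else n
        dyads.setdefault(iv.chrom, []).append(iv.center)
    sorted_dyads = {c: np.sort(np.asarray(d, dtype=np.int64)) for c, d in dyads.items()}
    empty = np.empty(0, dtype=np.int64)
    flags = [
        bool(_count_in(sorted_dyads.get(r.chrom, empty), r.start, r.end) > 0)
        for r in regions
    ]
    return sum(flags) / len(flags), flags
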