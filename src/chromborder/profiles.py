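"""Aggregate-signal machinery: anchored and binned meta-profiles,
dinucleotide profiles, and H2A.Z/mark enrichment statistics.

The anchored profile averages per-base coverage in a fixed window around a
set of anchors (TF binding summits, open-chromatin boundaries); minus-strand
anchors are mirrored so "+offset" always points the same biological way.
The binned body profile rescales regions of different widths onto a common
axis of ``n_bins`` body bins flanked by fixed-width flank bins; values are
mean per-base densities so regions of different widths are comparable.

Read-extension defaults follow the assays: 147 bp for MNase/nucleosome tags,
200 bp for histone ChIP, and no extension (single-bp cut sites) for DHS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, Tag, extend_reads

MNASE_EXTENSION = 147
CHIP_EXTENSION = 200

CG_SET = frozenset({"CC", "CG", "GC", "GG"})
AT_SET = frozenset({"AA", "AT", "TA", "TT"})


@dataclass
class SignalProfile:
    """A mean signal along an axis of bp offsets or bin indices."""

    axis: np.ndarray
    values: np.ndarray
    n_regions: int
    labels: list[str] | None = None
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.shape != self.values.shape:
            raise ValueError("axis and values must have the same shape")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"axis": self.axis, "value": self.values})
        if self.labels is not None:
            df["label"] = self.labels
        df["n"] = self.n_regions
        return df


class _IntervalIndex:
    """Per-chromosome sorted interval lists supporting window coverage."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.maxw: dict[str, int] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            arr = np.asarray(pairs, dtype=np.int64)
            self.starts[chrom] = arr[:, 0]
            self.ends[chrom] = arr[:, 1]
            self.maxw[chrom] = int((arr[:, 1] - arr[:, 0]).max())

    def window_coverage(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Per-base interval count over [lo, hi); lo may be negative."""
        width = hi - lo
        out = np.zeros(width, dtype=np.int64)
        starts = self.starts.get(chrom)
        if starts is None:
            return out
        ends = self.ends.get(chrom)
        i0 = int(np.searchsorted(starts, lo - self.maxw[chrom], side="left"))
        i1 = int(np.searchsorted(starts, hi, side="left"))
        if i0 == i1:
            return out
        s = np.clip(starts[i0:i1] - lo, 0, width)
        e = np.clip(ends[i0:i1] - lo, 0, width)
        keep = e > s
        diff = np.zeros(width + 1, dtype=np.int64)
        np.add.at(diff, s[keep], 1)
        np.add.at(diff, e[keep], -1)
        return np.cumsum(diff[:-1])


def _tag_intervals(
    tags: Iterable[Tag], extension: int | None
) -> list[GenomicInterval]:
    """Extended reads, or 1-bp cut-site points when extension is None."""
    if extension is not None:
        return extend_reads(tags, extension)
    return [GenomicInterval(t.chrom, t.cut_site, t.cut_site + 1, t.strand) for t in tags]


def boundary_anchors(
    regions: Iterable[GenomicInterval],
) -> list[tuple[str, int, str]]:
    """Both boundaries of each region as oriented anchors.

    The 5' boundary anchors at ``start`` on '+' and the 3' boundary at
    ``end`` on '-', so positive profile offsets always point into the region
    interior.
    """
    anchors: list[tuple[str, int, str]] = []
    for r in regions:
        anchors.append((r.chrom, r.start, "+"))
        anchors.append((r.chrom, r.end, "-"))
    return anchors


def anchored_profile(
    anchors: Sequence[tuple[str, int, str]],
    tags: Iterable[Tag],
    window: int,
    extension: int | None = None,
) -> SignalProfile:
    """Mean coverage profile in ``[-window, +window]`` around anchors.

    ``anchors`` are ``(chrom, position, strand)`` triples; minus-strand
    anchors mirror the offset axis. ``extension`` extends each tag to a
    fixed length before counting; ``None`` counts single-bp cut sites.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if window < 1:
        raise ValueError("window must be >= 1")
    index = _IntervalIndex(_tag_intervals(tags, extension))
    total = np.zeros(2 * window + 1, dtype=float)
    for chrom, pos, strand in anchors:
        cov = index.window_coverage(chrom, pos - window, pos + window + 1)
        if strand == "-":
            cov = cov[::-1]
        total += cov
    return SignalProfile(
        axis=np.arange(-window, window + 1),
        values=total / len(anchors),
        n_regions=len(anchors),
    )


def _mass(prefix: np.ndarray, cov: np.ndarray, x: float) -> float:
    """Continuous cumulative coverage mass at fractional coordinate x."""
    xi = int(np.floor(x))
    xi = max(0, min(xi, cov.size))
    frac = x - xi
    m = float(prefix[xi])
    if 0 <= xi < cov.size and frac > 0:
        m += frac * float(cov[xi])
    return m


def binned_body_profile(
    regions: Sequence[GenomicInterval],
    tags: Iterable[Tag],
    n_bins: int = 10,
    flank_bp: int = 1000,
    flank_bin_bp: int = 100,
    extension: int | None = None,
) -> SignalProfile:
    """Mean per-base tag density across scaled region bodies plus flanks.

    Each region's body is split into ``n_bins`` equal-width bins (fractional
    edges when the width does not divide evenly) and each flank into
    ``flank_bp / flank_bin_bp`` fixed-width bins. A tag contributes its bp
    overlap to each bin; a bin's value is the mean over regions of
    (overlap bp / bin width), i.e. mean per-base density, which makes bodies
    of different widths comparable.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not regions:
        raise ValueError("regions must be non-empty")
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    for r in regions:
        if r.width <= n_bins:
            raise ValueError("regions must be wider than n_bins bases")
    n_flank = flank_bp // flank_bin_bp
    index = _IntervalIndex(_tag_intervals(tags, extension))
    n_total = 2 * n_flank + n_bins
    acc = np.zeros(n_total, dtype=float)
    for r in regions:
        lo = r.start - flank_bp
        cov = index.window_coverage(r.chrom, lo, r.end + flank_bp)
        prefix = np.concatenate([[0], np.cumsum(cov)])
        edges = np.concatenate(
            [
                np.arange(0, flank_bp, flank_bin_bp, dtype=float),
                np.linspace(flank_bp, flank_bp + r.width, n_bins + 1),
                np.arange(
                    flank_bp + r.width + flank_bin_bp,
                    flank_bp + r.width + flank_bp + 1,
                    flank_bin_bp,
                    dtype=float,
                ),
            ]
        )
        masses = np.array([_mass(prefix, cov, e) for e in edges])
        widths = np.diff(edges)
        acc += np.diff(masses) / widths
    labels = (
        [f"flank5:{-flank_bp + i * flank_bin_bp}" for i in range(n_flank)]
        + [f"body:{i + 1}" for i in range(n_bins)]
        + [f"flank3:+{i * flank_bin_bp}" for i in range(n_flank)]
    )
    return SignalProfile(
        axis=np.arange(n_total),
        values=acc / len(regions),
        n_regions=len(regions),
        labels=labels,
    )


def dinucleotide_profile(
    sequences: Sequence[str],
    which: str = "cg",
    background: Sequence[str] | None = None,
) -> SignalProfile:
    """Positional dinucleotide-set frequency across aligned sequences.

    ``which`` selects the C/G set {CC, CG, GC, GG} or the A/T set
    {AA, AT, TA, TT}. The raw value at position ``p`` is the fraction of
    sequences whose dinucleotide at ``(p, p + 1)`` belongs to the set,
    with N-containing dinucleotides excluded from numerator and denominator.
    Reported values are raw / background-set frequency, where the background
    is computed from ``background`` sequences if given, else from the window
    mean of the raw profile.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1 or lengths.pop() < 2:
        raise ValueError("sequences must share one length >= 2")
    dset = {"cg": CG_SET, "at": AT_SET}.get(which.lower())
    if dset is None:
        raise ValueError("which must be 'cg' or 'at'")

    arr = np.array([list(s.upper()) for s in sequences])
    left, right = arr[:, :-1], arr[:, 1:]
    valid = (left != "N") & (right != "N")
    in_set = np.zeros_like(valid)
    for d in dset:
        in_set |= (left == d[0]) & (right == d[1])
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        raw = np.where(n_valid > 0, (in_set & valid).sum(axis=0) / n_valid, np.nan)

    if background is not None:
        bs = [s.upper() for s in background]
        n_in, n_ok = 0, 0
        for s in bs:
            for i in range(len(s) - 1):
                d = s[i : i + 2]
                if "N" in d:
                    continue
                n_ok += 1
                n_in += d in dset
        if n_ok == 0:
            raise ValueError("background sequences contain no valid dinucleotides")
        bg = n_in / n_ok
    else:
        bg = float(np.nanmean(raw))
    if bg == 0:
        raise ValueError("background set frequency is zero")
    return SignalProfile(
        axis=np.arange(arr.shape[1] - 1),
        values=raw / bg,
        n_regions=len(sequences),
        raw_values=raw,
    )


def _overlap_counts(
    intervals: Sequence[GenomicInterval], items: Iterable[GenomicInterval]
) -> np.ndarray:
    """Per-interval count of items whose span overlaps the interval."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for it in items:
        tmp.setdefault(it.chrom, []).append((it.start, it.end))
    for chrom, pairs in tmp.items():
        arr = np.asarray(pairs, dtype=np.int64)
        starts[chrom] = np.sort(arr[:, 0])
        ends[chrom] = np.sort(arr[:, 1])
    out = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        s = starts.get(iv.chrom)
        if s is None:
            continue
        e = ends[iv.chrom]
        n_right = s.size - np.searchsorted(s, iv.end, side="left")  # start >= end
        n_left = np.searchsorted(e, iv.start, side="right")  # end <= start
        out[i] = s.size - n_right - n_left
    return out


def h2az_enrichment(
    nucleosomes: Sequence[GenomicInterval],
    h2az_nucleosomes: Sequence[GenomicInterval],
    mark_tags: Mapping[str, Iterable[Tag]],
    h2az_tags: Iterable[Tag],
) -> pd.DataFrame:
    """Relative enrichment and H2A.Z correlation of histone marks.

    Per-nucleosome mark level = count of mark tags whose footprint overlaps
    the nucleosome. ``enrichment`` = mean level over nucleosomes intersecting
    an H2A.Z nucleosome / mean level over all nucleosomes (NaN when the
    overall mean is zero). ``h2az_rank_corr`` = Spearman correlation between
    per-nucleosome H2A.Z tag count and mark level over all nucleosomes; a
    mark with identical level on every nucleosome gets correlation 0.0 by
    convention (no rank information).
    """
    if not nucleosomes:
        raise ValueError("nucleosomes must be non-empty")
    member = _overlap_counts(nucleosomes, h2az_nucleosomes) > 0
    h2az_level = _overlap_counts(
        nucleosomes, (t.footprint for t in h2az_tags)
    ).astype(float)
    rows = {}
    for mark, tags in mark_tags.items():
        level = _overlap_counts(nucleosomes, (t.footprint for t in tags)).astype(float)
        overall = level.mean()
        if overall == 0:
            enr = np.nan
        elif not member.any():
            enr = np.nan
        else:
            enr = level[member].mean() / overall
        if np.ptp(level) == 0 or np.ptp(h2az_level) == 0:
            corr = 0.0
        else:
            corr = float(stats.spearmanr(h2az_level, level).statistic)
        rows[mark] = {"enrichment": enr, "h2az_rank_corr": corr}
    return pd.DataFrame.from_dict(rows, orient="index")
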