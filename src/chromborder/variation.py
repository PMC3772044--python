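"""Cross-strain comparison of open-chromatin geometry.

Given one reference strain's open-chromatin regions and the region sets of
the other strains (all mapped to the same reference assembly), this module
maps homologous regions by nearest same-kind anchor (5' end, center, or 3'
end), summarizes how often strain boundaries fall within a given distance of
the reference boundary, stratifies those summaries by the in vitro
nucleosome score of the underlying boundary sequence, builds the
boundary-distance trait matrix used for QTL mapping, and provides a
random-relocation shuffle control.

Sentinel convention: distances beyond the search radius are NaN; loci
carrying any sentinel are excluded from mean curves (their count is
reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, nearest_feature

ANCHOR_KINDS = ("end5", "center", "end3")


def _anchor_positions(
    regions: Sequence[GenomicInterval], anchor: str
) -> np.ndarray:
    if anchor == "end5":
        return np.array([r.start for r in regions], dtype=np.int64)
    if anchor == "center":
        return np.array([r.center for r in regions], dtype=np.int64)
    if anchor == "end3":
        return np.array([r.end for r in regions], dtype=np.int64)
    raise ValueError(f"anchor must be one of {ANCHOR_KINDS}")


def _region_ids(regions: Sequence[GenomicInterval]) -> list[str]:
    return [r.id if r.id is not None else f"r{i}" for i, r in enumerate(regions)]


def _positions_by_chrom(
    regions: Sequence[GenomicInterval], anchor: str
) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    pos = _anchor_positions(regions, anchor)
    for r, p in zip(regions, pos):
        out.setdefault(r.chrom, []).append(int(p))
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in out.items()}


def map_homologs(
    reference_regions: Sequence[GenomicInterval],
    strain_region_sets: Mapping[str, Sequence[GenomicInterval]],
    anchor: str = "end5",
    radius: int = 500,
) -> pd.DataFrame:
    """Signed distance from each reference anchor to its nearest strain homolog.

    ``D[locus, strain]`` = (strain anchor - reference anchor) for the nearest
    same-kind anchor in that strain, NaN when the nearest candidate is beyond
    ``radius`` (or the strain has no regions on the chromosome). The center
    anchor is the floored midpoint between the 5' and 3' boundaries. Nearest
    ties break toward the smaller coordinate.
    """
    if anchor not in ANCHOR_KINDS:
        raise ValueError(f"anchor must be one of {ANCHOR_KINDS}")
    ids = _region_ids(reference_regions)
    ref_pos = _anchor_positions(reference_regions, anchor)
    D = pd.DataFrame(
        np.nan, index=ids, columns=list(strain_region_sets), dtype=float
    )
    for strain, regions in strain_region_sets.items():
        by_chrom = _positions_by_chrom(regions, anchor)
        col = np.full(len(ids), np.nan)
        for i, (ref, pos) in enumerate(zip(reference_regions, ref_pos)):
            feats = by_chrom.get(ref.chrom)
            if feats is None:
                continue
            hit = nearest_feature(int(pos), feats, max_dist=radius)
            if hit is not None:
                col[i] = hit[1]
        D[strain] = col
    return D


@dataclass
class OverlapFrequency:
    """Per-locus strain-match counts along a distance grid, plus mean curve."""

    per_locus: pd.DataFrame
    mean_curve: pd.Series
    mode: str
    n_excluded: int = 0


def overlap_frequency(
    D: pd.DataFrame,
    distances: Sequence[int] | None = None,
    mode: str = "cumulative",
) -> OverlapFrequency:
    """Number of strains matching each locus within each distance.

    ``cumulative``: entry(l, d) = number of strains with ``|D[l, s]| <= d``
    (non-decreasing in d, bounded by strain count). ``per-bin``: counts in
    the right-closed bin ``(d - step, d]``, the first bin using the grid's
    first step. Loci with any sentinel (NaN) are excluded from the mean
    curve; their count is reported in ``n_excluded``.
    """
    if mode not in ("cumulative", "per-bin"):
        raise ValueError("mode must be 'cumulative' or 'per-bin'")
    grid = np.asarray(
        distances if distances is not None else np.arange(0, 151, 5), dtype=float
    )
    if grid.size < 1 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("distance grid must be strictly increasing")
    absd = D.abs().to_numpy()
    cum = (absd[:, :, None] <= grid[None, None, :]).sum(axis=1)
    if mode == "per-bin":
        step0 = grid[1] - grid[0] if grid.size > 1 else grid[0] + 1
        below = (absd[:, :, None] <= (grid - np.concatenate([[step0], np.diff(grid)]))[None, None, :]).sum(axis=1)
        vals = cum - below
    else:
        vals = cum
    per_locus = pd.DataFrame(vals, index=D.index, columns=grid)
    complete = ~D.isna().any(axis=1)
    mean_curve = per_locus.loc[complete].mean(axis=0)
    return OverlapFrequency(
        per_locus=per_locus,
        mean_curve=mean_curve,
        mode=mode,
        n_excluded=int((~complete).sum()),
    )


def stratify_by_score(
    per_locus: pd.DataFrame,
    scores: pd.Series,
    low_cut: float = 0.0,
    high_cut: float = 0.5,
) -> dict[str, pd.Series]:
    """Mean overlap-frequency curves per in vitro nucleosome score stratum.

    Loci partition into ``low`` (score < low_cut), ``high`` (score >
    high_cut) and ``mid`` (everything else, boundary values included, since
    the cuts are strict). Empty strata yield empty series, not errors.
    """
    scores = scores.reindex(per_locus.index)
    out: dict[str, pd.Series] = {}
    masks = {
        "low": scores < low_cut,
        "mid": (scores >= low_cut) & (scores <= high_cut),
        "high": scores > high_cut,
    }
    for name, mask in masks.items():
        sub = per_locus.loc[mask.fillna(False)]
        out[name] = sub.mean(axis=0) if len(sub) else pd.Series(dtype=float)
    return out


@dataclass
class BoundaryTraitMatrix:
    """Boundary loci x strains nearest end-to-end distances.

    Rows are boundary loci named ``"<region id>:5p"`` / ``"<region id>:3p"``;
    values are unsigned nearest end-to-end distances in bp, all below the
    retention cutoff used at construction. ``positions`` carries the genomic
    coordinate of each retained boundary.
    """

    values: pd.DataFrame
    positions: pd.DataFrame
    cutoff: float = 100.0

    @property
    def n_strains(self) -> int:
        return self.values.shape[1]

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)


def _boundary_candidates(
    reference_regions: Sequence[GenomicInterval],
) -> list[tuple[str, str, str, int]]:
    """(boundary id, side, chrom, position) for both ends of each region."""
    ids = _region_ids(reference_regions)
    out = []
    for rid, r in zip(ids, reference_regions):
        out.append((f"{rid}:5p", "5p", r.chrom, r.start))
        out.append((f"{rid}:3p", "3p", r.chrom, r.end))
    return out


def build_boundary_traits(
    reference_regions: Sequence[GenomicInterval],
    strain_region_sets: Mapping[str, Sequence[GenomicInterval]],
    cutoff: float = 100.0,
) -> BoundaryTraitMatrix:
    """Boundary-distance trait matrix for QTL mapping.

    Each reference region contributes two candidate boundary loci (5' and
    3'). For every strain the trait value is the unsigned distance from the
    reference boundary to the nearest same-side region end in that strain;
    a boundary is retained only when this distance is strictly below
    ``cutoff`` in every strain.
    """
    strains = list(strain_region_sets)
    if len(strains) < 2:
        raise ValueError("need at least 2 strains")
    cands = _boundary_candidates(reference_regions)
    ends_by_strain: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for strain, regions in strain_region_sets.items():
        ends_by_strain[strain] = {
            "5p": _positions_by_chrom(regions, "end5"),
            "3p": _positions_by_chrom(regions, "end3"),
        }
    rows, meta = [], []
    for bid, side, chrom, pos in cands:
        dists = np.empty(len(strains))
        for j, strain in enumerate(strains):
            feats = ends_by_strain[strain][side].get(chrom)
            hit = nearest_feature(pos, feats, None) if feats is not None else None
            dists[j] = abs(hit[1]) if hit is not None else np.inf
        if np.all(dists < cutoff):
            rows.append(dists)
            meta.append((bid, chrom, pos, bid.rsplit(":", 1)[0], side))
    if not rows:
        warnings.warn("no boundary passed the all-strain distance cutoff")
        values = pd.DataFrame(columns=strains, dtype=float)
        positions = pd.DataFrame(columns=["chrom", "pos", "region_id", "side"])
        return BoundaryTraitMatrix(values, positions, cutoff)
    index = [m[0] for m in meta]
    values = pd.DataFrame(np.vstack(rows), index=index, columns=strains)
    positions = pd.DataFrame(
        [(m[1], m[2], m[3], m[4]) for m in meta],
        index=index,
        columns=["chrom", "pos", "region_id", "side"],
    )
    return BoundaryTraitMatrix(values, positions, cutoff)


def shuffle_control(
    reference_regions: Sequence[GenomicInterval],
    strain_region_sets: Mapping[str, Sequence[GenomicInterval]],
    chrom_lengths: Mapping[str, int],
    n_shuffles: int = 10,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Null nearest-distance distributions from random region relocation.

    Each shuffle relocates every strain region uniformly within its
    chromosome (width preserved, overlaps allowed) and recomputes the
    center-to-center and end-to-end nearest unsigned distances from each
    reference region; returns the pooled distributions under keys
    ``'center'`` and ``'end'`` (5' and 3' boundaries pooled).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for regions in strain_region_sets.values():
        for r in regions:
            if r.chrom not in chrom_lengths:
                raise ValueError(f"no chromosome length for {r.chrom}")
            if r.width > chrom_lengths[r.chrom]:
                raise ValueError(
                    f"region wider than chromosome {r.chrom}: {r.width} bp"
                )
    rng = np.random.default_rng(seed)
    pooled: dict[str, list[float]] = {"center": [], "end": []}
    for _ in range(n_shuffles):
        shuffled: dict[str, list[GenomicInterval]] = {}
        for strain, regions in strain_region_sets.items():
            moved = []
            for r in regions:
                start = int(rng.integers(0, chrom_lengths[r.chrom] - r.width + 1))
                moved.append(
                    GenomicInterval(r.chrom, start, start + r.width, r.strand, r.id)
                )
            shuffled[strain] = moved
        dists = observed_nearest_distances(reference_regions, shuffled)
        pooled["center"].extend(dists["center"])
        pooled["end"].extend(dists["end"])
    return {k: np.asarray(v, dtype=float) for k, v in pooled.items()}


def observed_nearest_distances(
    reference_regions: Sequence[GenomicInterval],
    strain_region_sets: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, np.ndarray]:
    """Unsigned nearest center-to-center and end-to-end distances, pooled.

    The end distribution pools 5' end-to-5' end and 3' end-to-3' end
    distances across all reference regions and strains. Reference regions
    with no strain region on the same chromosome are skipped.
    """
    out: dict[str, list[float]] = {"center": [], "end": []}
    for strain, regions in strain_region_sets.items():
        centers = _positions_by_chrom(regions, "center")
        starts = _positions_by_chrom(regions, "end5")
        ends = _positions_by_chrom(regions, "end3")
        for ref in reference_regions:
            c = centers.get(ref.chrom)
            if c is None:
                continue
            hit = nearest_feature(ref.center, c, None)
            if hit is not None:
                out["center"].append(abs(hit[1]))
            for pos, feats in ((ref.start, starts[ref.chrom]), (ref.end, ends[ref.chrom])):
                hit = nearest_feature(pos, feats, None)
                if hit is not None:
                    out["end"].append(abs(hit[1]))
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}
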