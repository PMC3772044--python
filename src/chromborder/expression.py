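"""Linking boundary variation to nearby gene expression.

A gene whose transcription start site (tss) lies within 1 kb of an
open-chromatin region has a tss-facing boundary — the region end nearer to
the tss. This module identifies that boundary, compares expression between
genotype groups at a marker, correlates boundary distance with expression,
and summarizes the overlap of two QTL record sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval


@dataclass
class GeneRecord:
    """A gene with an annotated tss position inside its span."""

    id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"tss must lie within the gene span for {self.id}")


def tss_facing_boundary(
    region: GenomicInterval, gene: GeneRecord, max_tss_dist: int = 1000
) -> str | None:
    """Which region end faces the gene's tss: '5p', '3p', or None.

    Returns ``None`` when the tss is on another chromosome or more than
    ``max_tss_dist`` bp from the region (distance 0 inside the region).
    Otherwise the side whose end coordinate is nearer the tss; equidistant
    ties go to '5p'.
    """
    if region.chrom != gene.chrom:
        return None
    gap = max(0, region.start - gene.tss, gene.tss - region.end)
    if gap > max_tss_dist:
        return None
    return "5p" if abs(region.start - gene.tss) <= abs(region.end - gene.tss) else "3p"


@dataclass
class GroupComparison:
    mean_rm: float
    mean_by: float
    n_rm: int
    n_by: int
    statistic: float
    pvalue: float

    @property
    def mean_difference(self) -> float:
        return self.mean_by - self.mean_rm


def genotype_group_compare(
    values: Sequence[float] | np.ndarray,
    genotypes: Sequence[float] | np.ndarray,
) -> GroupComparison:
    """Compare a per-strain quantity between the two genotype groups.

    Strains are split by genotype 0 (RM) vs 1 (BY); missing (0.5) strains
    are excluded. Reports group means and the Wilcoxon rank-sum
    (Mann-Whitney U) statistic with the tie-corrected normal-approximation
    two-sided p value.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if v.shape != g.shape:
        raise ValueError("values and genotypes must have the same length")
    rm = v[g == 0]
    by = v[g == 1]
    if rm.size < 2 or by.size < 2:
        raise ValueError("need at least 2 strains in each genotype group")
    res = stats.mannwhitneyu(rm, by, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        mean_rm=float(rm.mean()),
        mean_by=float(by.mean()),
        n_rm=int(rm.size),
        n_by=int(by.size),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


def distance_expression_correlation(
    trait: Sequence[float] | np.ndarray,
    expression: Sequence[float] | np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between boundary distance and expression across strains.

    Missing entries (NaN in either vector) are dropped pairwise; at least 3
    complete pairs are required. Returns ``(r, p)``; ``(nan, nan)`` when
    either vector has zero variance.
    """
    t = np.asarray(trait, dtype=float)
    e = np.asarray(expression, dtype=float)
    if t.shape != e.shape:
        raise ValueError("trait and expression must have the same length")
    ok = np.isfinite(t) & np.isfinite(e)
    t, e = t[ok], e[ok]
    if t.size < 3:
        raise ValueError("need at least 3 complete strain pairs")
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        res = stats.pearsonr(t, e)
    elif method == "spearman":
        res = stats.spearmanr(t, e)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


@dataclass
class OverlapResult:
    """Bidirectional key overlap between two association record sets."""

    fraction_ab: float
    fraction_ba: float
    shared: list[str]


def dual_qtl_overlap(
    records_a: pd.DataFrame | Iterable[str],
    records_b: pd.DataFrame | Iterable[str],
    key: str = "marker",
) -> OverlapResult:
    """Overlap of the key sets of two QTL record sets, both directions.

    Accepts record frames (the ``key`` column is used, 'marker' or 'trait')
    or raw key iterables. Fractions are |A ∩ B| / |A| and |A ∩ B| / |B|;
    NaN when the respective set is empty.
    """
    if key not in ("marker", "trait"):
        raise ValueError("key must be 'marker' or 'trait'")

    def _keys(obj) -> set[str]:
        if isinstance(obj, pd.DataFrame):
            return set(obj[key].astype(str))
        return set(map(str, obj))

    a, b = _keys(records_a), _keys(records_b)
    shared = a & b
    return OverlapResult(
        fraction_ab=len(shared) / len(a) if a else float("nan"),
        fraction_ba=len(shared) / len(b) if b else float("nan"),
        shared=sorted(shared),
    )


def link_genes(
    genes: Sequence[GeneRecord],
    regions: Sequence[GenomicInterval],
    traits,
    expression: pd.DataFrame,
    max_tss_dist: int = 1000,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene link report: facing boundary and trait-expression correlation.

    For every gene whose tss lies within ``max_tss_dist`` of a region, and
    whose facing boundary is present in the trait matrix, reports the facing
    side and the correlation of the facing (and, when retained, the
    opposite) boundary trait with the gene's expression. ``traits`` is a
    :class:`~chromborder.variation.BoundaryTraitMatrix`.
    """
    region_by_id = {
        (r.id if r.id is not None else f"r{i}"): r for i, r in enumerate(regions)
    }
    strains = [s for s in traits.strains if s in expression.columns]
    rows = []
    for gene in genes:
        if gene.id not in expression.index:
            continue
        for rid, region in region_by_id.items():
            side = tss_facing_boundary(region, gene, max_tss_dist)
            if side is None:
                continue
            facing_id = f"{rid}:{side}"
            if facing_id not in traits.values.index:
                continue
            expr = expression.loc[gene.id, strains].to_numpy(dtype=float)
            r, p = distance_expression_correlation(
                traits.values.loc[facing_id, strains].to_numpy(dtype=float),
                expr,
                method=method,
            )
            other_id = f"{rid}:{'3p' if side == '5p' else '5p'}"
            if other_id in traits.values.index:
                r_other, _ = distance_expression_correlation(
                    traits.values.loc[other_id, strains].to_numpy(dtype=float),
                    expr,
                    method=method,
                )
            else:
                r_other = float("nan")
            rows.append(
                {
                    "gene": gene.id,
                    "region": rid,
                    "facing_side": side,
                    "facing_trait": facing_id,
                    "r_facing": r,
                    "p_facing": p,
                    "r_opposite": r_other,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "region", "facing_side", "facing_trait",
            "r_facing", "p_facing", "r_opposite",
        ],
    )
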