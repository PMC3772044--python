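"""Boundary-shift QTL mapping.

The phenotype is the unsigned end-to-end distance of each retained
open-chromatin boundary across a recombinant cross; the genotype is a
markers x strains matrix on the {0, 0.5, 1} scale (0: RM allele, 0.5:
missing, 1: BY allele). The association statistic is the absolute Pearson
correlation between a genotype row and a trait row, with the 0.5 code acting
as an uninformative midpoint. Significance comes from a strain-label
permutation test — one random permutation of the strain labels is applied to
the whole trait matrix per iteration, preserving inter-trait correlation —
with Benjamini-Hochberg FDR over all marker-trait pairs. Associations are
cis when the marker lies within 100 kb of the boundary on the same
chromosome, trans otherwise; markers with more than five trans linkages are
reported as hotspots.

The public surface follows the Model/Results convention:

>>> model = BoundaryQTL(genotypes, traits)          # doctest: +SKIP
>>> res = model.fit(n_perm=1000, seed=1)            # doctest: +SKIP
>>> res.significant(fdr=0.01)                       # doctest: +SKIP
>>> print(res.summary())                            # doctest: +SKIP

Two permutation-null conventions are available. ``null="perpair"`` compares
each pair's observed statistic with its own permuted replicates, giving a
minimum attainable p of 1/(n_perm + 1). ``null="pooled"`` compares each
observed statistic with the permuted statistics pooled over all pairs,
which resolves far smaller p values from the same number of permutations
and is what genome-scale scans need to clear a BH threshold of 0.01 over
tens of thousands of pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .variation import BoundaryTraitMatrix


@dataclass
class GenotypeMatrix:
    """Markers x strains genotypes with marker spans.

    ``values`` holds genotypes on the {0, 0.5, 1} scale (fractional values
    appear after marker merging and are permitted when ``merged=True``);
    ``spans`` is indexed by marker id with columns ``chrom``, ``start``,
    ``end``, position-sorted within each chromosome.
    """

    values: pd.DataFrame
    spans: pd.DataFrame
    merged: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.spans.index):
            raise ValueError("values and spans must share the same marker index")
        for col in ("chrom", "start", "end"):
            if col not in self.spans.columns:
                raise ValueError(f"spans must have a '{col}' column")
        if not self.merged:
            vals = self.values.to_numpy(dtype=float)
            if not np.isin(vals, (0.0, 0.5, 1.0)).all():
                raise ValueError("genotype values must be in {0, 0.5, 1}")
        for _, grp in self.spans.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise ValueError("markers must be position-sorted within chromosomes")

    @property
    def n_strains(self) -> int:
        return self.values.shape[1]

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    @property
    def markers(self) -> list[str]:
        return list(self.values.index)


def merge_markers(genotypes: GenotypeMatrix, max_mismatch: int = 2) -> GenotypeMatrix:
    """Merge adjacent near-identical markers into average profiles.

    Greedy left-to-right chaining within each chromosome: a chain extends
    while the next marker differs from the previous raw marker at no more
    than ``max_mismatch`` strains, where strains with a missing (0.5) value
    in either marker are excluded from the mismatch count. Each chain
    collapses to the per-strain mean of its members, spanning the union of
    member spans; the merged marker keeps the first member's id.
    """
    vals = genotypes.values
    spans = genotypes.spans
    merged_vals, merged_spans, index = [], [], []
    for chrom, grp in spans.groupby("chrom", sort=False):
        ids = list(grp.index)
        chain = [ids[0]]
        for prev, cur in zip(ids, ids[1:]):
            a = vals.loc[prev].to_numpy(dtype=float)
            b = vals.loc[cur].to_numpy(dtype=float)
            informative = (a != 0.5) & (b != 0.5)
            mismatches = int(np.sum((a != b) & informative))
            if mismatches <= max_mismatch:
                chain.append(cur)
            else:
                merged_vals.append(vals.loc[chain].mean(axis=0))
                merged_spans.append(
                    (chrom, int(spans.loc[chain, "start"].min()),
                     int(spans.loc[chain, "end"].max()), len(chain))
                )
                index.append(chain[0])
                chain = [cur]
        merged_vals.append(vals.loc[chain].mean(axis=0))
        merged_spans.append(
            (chrom, int(spans.loc[chain, "start"].min()),
             int(spans.loc[chain, "end"].max()), len(chain))
        )
        index.append(chain[0])
    values = pd.DataFrame(merged_vals, index=index)
    spans_df = pd.DataFrame(
        merged_spans, index=index, columns=["chrom", "start", "end", "n_members"]
    )
    return GenotypeMatrix(values, spans_df, merged=True)


def _standardize_rows(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so Z @ Z.T yields Pearson correlations; flags zero-variance rows."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe = np.where(sd == 0, 1.0, sd)
    Z = (M - mu) / safe / np.sqrt(M.shape[1])
    Z[flat] = 0.0
    return Z, flat


def associate(
    genotypes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute Pearson correlation between every marker and trait row.

    Both frames must cover the same strains; ``traits`` is reordered to the
    genotype strain order. Zero-variance rows yield statistic 0 and are
    flagged in the second return value (markers x traits boolean frame).
    """
    if set(genotypes.columns) != set(traits.columns):
        raise ValueError("genotypes and traits must cover the same strains")
    traits = traits[genotypes.columns]
    n = genotypes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 strains")
    G, gflat = _standardize_rows(genotypes.to_numpy(dtype=float))
    T, tflat = _standardize_rows(traits.to_numpy(dtype=float))
    A = np.abs(G @ T.T)
    flagged = np.logical_or.outer(gflat, tflat)
    return (
        pd.DataFrame(A, index=genotypes.index, columns=traits.index),
        pd.DataFrame(flagged, index=genotypes.index, columns=traits.index),
    )


def permutation_fdr(
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    null: str = "perpair",
) -> pd.DataFrame:
    """Permutation P values and BH FDR for every marker-trait pair.

    Each of the ``n_perm`` iterations applies one random strain-label
    permutation to the whole trait matrix and recomputes the statistic.
    Per-pair null: ``p = (1 + #{A* >= A}) / (n_perm + 1)`` using the pair's
    own permuted replicates. Pooled null: the count runs over the permuted
    statistics of all pairs, so ``p = (1 + #) / (n_perm * n_pairs + 1)``.
    FDR is Benjamini-Hochberg step-up over all pairs. Returns a tidy frame
    with columns ``marker, trait, stat, p, fdr``.
    """
    if null not in ("perpair", "pooled"):
        raise ValueError("null must be 'perpair' or 'pooled'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a minimum attainable per-pair p of "
            f"{1 / (n_perm + 1):.3g}; FDR resolution will be coarse"
        )
    traits = traits[genotypes.columns]
    G, gflat = _standardize_rows(genotypes.to_numpy(dtype=float))
    T, tflat = _standardize_rows(traits.to_numpy(dtype=float))
    if genotypes.shape[1] < 3:
        raise ValueError("need at least 3 strains")
    A = np.abs(G @ T.T)
    n_pairs = A.size
    rng = np.random.default_rng(seed)
    if null == "perpair":
        exceed = np.zeros_like(A, dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(T.shape[1])
            Astar = np.abs(G @ T[:, perm].T)
            exceed += Astar >= A
        p = (1 + exceed) / (n_perm + 1)
    else:
        a_flat = A.ravel()
        exceed_flat = np.zeros(n_pairs, dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(T.shape[1])
            Astar = np.abs(G @ T[:, perm].T).ravel()
            Astar.sort()
            exceed_flat += n_pairs - np.searchsorted(Astar, a_flat, side="left")
        p = ((1 + exceed_flat) / (n_perm * n_pairs + 1)).reshape(A.shape)
    fdr = multipletests(p.ravel(), method="fdr_bh")[1].reshape(A.shape)
    flagged = np.logical_or.outer(gflat, tflat)
    records = pd.DataFrame(
        {
            "marker": np.repeat(genotypes.index.to_numpy(), traits.shape[0]),
            "trait": np.tile(traits.index.to_numpy(), genotypes.shape[0]),
            "stat": A.ravel(),
            "p": p.ravel(),
            "fdr": fdr.ravel(),
            "degenerate": flagged.ravel(),
        }
    )
    return records


def classify_associations(
    records: pd.DataFrame,
    marker_spans: pd.DataFrame,
    trait_positions: pd.DataFrame,
    cis_window: int = 100_000,
) -> pd.DataFrame:
    """Add a cis/trans class column to association records.

    An association is cis iff marker and boundary share a chromosome and the
    gap between the marker span and the boundary position is <= ``cis_window``
    (a boundary inside the span has gap 0); otherwise trans.
    """
    out = records.copy()
    mchrom = marker_spans["chrom"]
    mstart = marker_spans["start"]
    mend = marker_spans["end"]
    tchrom = trait_positions["chrom"]
    tpos = trait_positions["pos"]
    m = out["marker"].map(mchrom)
    t = out["trait"].map(tchrom)
    s = out["marker"].map(mstart).to_numpy(dtype=float)
    e = out["marker"].map(mend).to_numpy(dtype=float)
    p = out["trait"].map(tpos).to_numpy(dtype=float)
    gap = np.maximum(0, np.maximum(s - p, p - e))
    cis = (m.to_numpy() == t.to_numpy()) & (gap <= cis_window)
    out["class"] = np.where(cis, "cis", "trans")
    return out


def find_hotspots(records: pd.DataFrame, min_links: int = 5) -> pd.DataFrame:
    """Markers with strictly more than ``min_links`` trans associations.

    ``records`` should already be filtered to the FDR threshold of interest.
    Returns a frame with ``marker`` and ``n_trans`` sorted by descending
    count.
    """
    trans = records[records["class"] == "trans"]
    counts = trans.groupby("marker").size()
    hot = counts[counts > min_links].sort_values(ascending=False)
    return hot.rename("n_trans").reset_index()


def annotate_candidates(
    marker_spans: pd.DataFrame,
    genes: pd.DataFrame,
    keyword_genes: Iterable[str] | None = None,
    window: int = 10_000,
) -> dict[str, list[str]]:
    """Candidate genes within ``window`` bp of each marker span.

    ``genes`` needs columns ``id``, ``chrom``, ``start``, ``end``. A gene is
    a candidate when its span overlaps ``[span.start - window,
    span.end + window]``. If ``keyword_genes`` is given the candidates are
    intersected with it.
    """
    keywords = set(keyword_genes) if keyword_genes is not None else None
    out: dict[str, list[str]] = {}
    for marker, row in marker_spans.iterrows():
        lo = row["start"] - window
        hi = row["end"] + window
        sel = genes[
            (genes["chrom"] == row["chrom"])
            & (genes["start"] <= hi)
            & (genes["end"] >= lo)
        ]
        ids = set(sel["id"])
        if keywords is not None:
            ids &= keywords
        out[str(marker)] = sorted(ids)
    return out


class BoundaryQTL:
    """Association model between cross genotypes and boundary-distance traits.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Markers x strains on the {0, 0.5, 1} scale, with marker spans.
    traits : BoundaryTraitMatrix
        Boundary loci x strains unsigned end-to-end distances.

    Strains are intersected and aligned; at least 3 shared strains are
    required. ``fit`` runs the permutation scan and returns a
    :class:`BoundaryQTLResults`.
    """

    def __init__(self, genotypes: GenotypeMatrix, traits: BoundaryTraitMatrix):
        shared = [s for s in genotypes.strains if s in set(traits.strains)]
        if len(shared) < 3:
            raise ValueError("need at least 3 shared strains")
        self.genotypes = genotypes
        self.traits = traits
        self.strains = shared
        self._G = genotypes.values[shared]
        self._T = traits.values[shared]

    @classmethod
    def from_frames(
        cls,
        genotype_values: pd.DataFrame,
        marker_spans: pd.DataFrame,
        trait_values: pd.DataFrame,
        trait_positions: pd.DataFrame,
    ) -> "BoundaryQTL":
        return cls(
            GenotypeMatrix(genotype_values, marker_spans, merged=True),
            BoundaryTraitMatrix(trait_values, trait_positions),
        )

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        null: str = "perpair",
        cis_window: int = 100_000,
    ) -> "BoundaryQTLResults":
        records = permutation_fdr(self._G, self._T, n_perm=n_perm, seed=seed, null=null)
        records = classify_associations(
            records, self.genotypes.spans, self.traits.positions, cis_window
        )
        stats, _ = associate(self._G, self._T)
        return BoundaryQTLResults(
            model=self,
            records=records,
            stat_matrix=stats,
            n_perm=n_perm,
            null=null,
            cis_window=cis_window,
        )


class BoundaryQTLResults:
    """Fitted boundary-QTL scan: statistics, permutation p, FDR, classes."""

    def __init__(
        self,
        model: BoundaryQTL,
        records: pd.DataFrame,
        stat_matrix: pd.DataFrame,
        n_perm: int,
        null: str,
        cis_window: int,
    ):
        self.model = model
        self.records = records
        self.stat_matrix = stat_matrix
        self.n_perm = n_perm
        self.null = null
        self.cis_window = cis_window

    def significant(self, fdr: float = 0.01) -> pd.DataFrame:
        """Association records passing the FDR threshold."""
        return self.records[self.records["fdr"] <= fdr].reset_index(drop=True)

    def hotspots(self, fdr: float = 0.01, min_links: int = 5) -> pd.DataFrame:
        return find_hotspots(self.significant(fdr), min_links=min_links)

    def candidate_genes(
        self,
        genes: pd.DataFrame,
        keyword_genes: Iterable[str] | None = None,
        window: int = 10_000,
        fdr: float = 0.01,
        min_links: int = 5,
    ) -> dict[str, list[str]]:
        """Candidate genes near hotspot markers."""
        hot = self.hotspots(fdr=fdr, min_links=min_links)
        spans = self.model.genotypes.spans.loc[hot["marker"]]
        return annotate_candidates(spans, genes, keyword_genes, window)

    def linked_trait_fractions(self, fdr: float = 0.01) -> dict[str, float]:
        """Fraction of traits with >= 1 cis / trans association at the FDR."""
        sig = self.significant(fdr)
        n_traits = self.model._T.shape[0]
        out = {}
        for cls in ("cis", "trans"):
            linked = sig.loc[sig["class"] == cls, "trait"].nunique()
            out[cls] = linked / n_traits if n_traits else float("nan")
        return out

    def summary(self, fdr: float = 0.01) -> str:
        sig = self.significant(fdr)
        n_cis = int((sig["class"] == "cis").sum())
        n_trans = int((sig["class"] == "trans").sum())
        frac = self.linked_trait_fractions(fdr)
        lines = [
            "Boundary QTL mapping",
            "=" * 48,
            f"strains:            {len(self.model.strains)}",
            f"markers:            {self.model._G.shape[0]}",
            f"boundary traits:    {self.model._T.shape[0]}",
            f"permutations:       {self.n_perm} ({self.null} null)",
            f"cis window:         {self.cis_window / 1000:.0f} kb",
            f"associations (FDR {fdr:g}): {len(sig)}",
        ]
        if len(sig):
            lines += [
                f"  cis:              {n_cis} ({100 * n_cis / len(sig):.1f}%)",
                f"  trans:            {n_trans} ({100 * n_trans / len(sig):.1f}%)",
            ]
        lines += [
            f"traits linked in cis:   {100 * frac['cis']:.1f}%",
            f"traits linked in trans: {100 * frac['trans']:.1f}%",
        ]
        return "\n".join(lines)
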