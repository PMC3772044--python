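"""Synthetic study generator.

Emulates the full data layout of a recombinant-cross open-chromatin study:
a two-allele cross with Markovian linkage on the {0, 0.5, 1} genotype scale
(0: RM, 0.5: missing, 1: BY), a reference set of open-chromatin loci whose
boundaries carry in vitro nucleosome occupancy scores, per-strain region
sets whose boundaries are displaced by planted marker effects plus
score-coupled noise, sequencing-tag tracks with boundary nucleosomes planted
just inside region edges, genomic sequence with elevated C/G dinucleotide
frequency at boundaries, and gene expression correlated with the tss-facing
boundary distance. Every planted effect is recorded in a
:class:`TruthManifest` so downstream stages can be scored against ground
truth.

Planted boundary effects are anchored at the BY allele: a strain's boundary
sits at the reference when its genotype at the planted marker is 1 (BY),
and ``2 * effect_bp`` away when it is 0 (RM), with missing (0.5) midway.
This mirrors the real design, where the reference strain is itself the BY
parent of the cross, and keeps the group-mean position difference equal to
``2 * effect_bp`` while leaving the unsigned end-to-end trait informative.

Boundary noise is Gaussian with standard deviation
``noise_sd_bp * (1 + invitro_noise_gain * max(score, 0))`` so that
sequence-encoded nucleosome preference (positive in vitro score) inflates
positional variance, the ordering the analysis stages are expected to
recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cbio
from .core import GenomicInterval, Tag
from .expression import GeneRecord, tss_facing_boundary
from .qtl import GenotypeMatrix
from .variation import BoundaryTraitMatrix, build_boundary_traits

DEFAULT_GENOME = {f"chr{i + 1:02d}": 150_000 for i in range(10)}

ASSAYS = ("mnase", "dhs", "faire", "h2az", "h3k27ac", "h3k4me1")


@dataclass
class TruthManifest:
    """Ground truth of every planted effect in a synthetic study."""

    planted_qtls: list[dict] = field(default_factory=list)
    nucleosome_offsets: dict = field(default_factory=dict)
    expression_effects: list[dict] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    clipped: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_cross(
    n_strains: int = 96,
    chrom_lengths: Mapping[str, int] | None = None,
    marker_spacing: int = 5_000,
    recomb_prob: float = 0.02,
    missing_rate: float = 0.02,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate cross genotypes with Markovian linkage.

    Per strain and chromosome the first marker is 0 or 1 with probability
    1/2 and each subsequent marker flips with probability ``recomb_prob``;
    entries are then independently replaced by 0.5 (missing) with
    probability ``missing_rate``. Markers are evenly spaced 1-bp spans, at
    least one per chromosome.
    """
    if not (0 <= recomb_prob <= 0.5):
        raise ValueError("recomb_prob must be in [0, 0.5]")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    genome = dict(chrom_lengths or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    strains = [f"s{i + 1:03d}" for i in range(n_strains)]
    blocks, spans, ids = [], [], []
    for chrom, length in genome.items():
        pos = np.arange(marker_spacing // 2, length, marker_spacing, dtype=np.int64)
        if pos.size == 0:
            pos = np.array([length // 2], dtype=np.int64)
        k = pos.size
        first = rng.integers(0, 2, size=n_strains)
        flips = rng.random((n_strains, k - 1)) < recomb_prob
        geno = np.empty((n_strains, k), dtype=np.int64)
        geno[:, 0] = first
        if k > 1:
            geno[:, 1:] = (first[:, None] + np.cumsum(flips, axis=1)) % 2
        vals = geno.astype(float)
        missing = rng.random((n_strains, k)) < missing_rate
        vals[missing] = 0.5
        blocks.append(vals.T)
        for j, p in enumerate(pos):
            ids.append(f"{chrom}:mk{j + 1:04d}")
            spans.append((chrom, int(p), int(p) + 1))
    values = pd.DataFrame(np.vstack(blocks), index=ids, columns=strains)
    spans_df = pd.DataFrame(spans, index=ids, columns=["chrom", "start", "end"])
    return GenotypeMatrix(values, spans_df)


def generate_loci(
    n_loci: int,
    width_range: tuple[int, int] = (300, 800),
    genome: Mapping[str, int] | None = None,
    min_gap: int = 1_000,
    seed: int | None = None,
) -> tuple[list[GenomicInterval], pd.Series]:
    """Non-overlapping reference open-chromatin loci with boundary scores.

    Loci are placed chromosome by chromosome with gaps of at least
    ``min_gap`` bp. Each locus carries one in vitro nucleosome occupancy
    score per boundary, drawn from an equal mixture of a nucleosome-poor
    stratum (uniform on [-1, 0)) and a nucleosome-favouring stratum
    (uniform on (0.5, 2]); the returned series is indexed
    ``"<locus id>:5p"`` / ``"<locus id>:3p"``.
    """
    if width_range[0] < 200:
        raise ValueError("locus widths must be >= 200 bp")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    loci: list[GenomicInterval] = []
    chroms = list(genome)
    per_chrom_target = int(np.ceil(n_loci / len(chroms)))
    count = 0
    for chrom in chroms:
        length = genome[chrom]
        cursor = int(rng.integers(min_gap, 2 * min_gap))
        placed = 0
        while placed < per_chrom_target and count < n_loci:
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            if cursor + width + min_gap > length:
                break
            count += 1
            placed += 1
            loci.append(
                GenomicInterval(chrom, cursor, cursor + width, ".", f"L{count:04d}")
            )
            cursor += width + min_gap + int(rng.integers(0, min_gap))
    if count < n_loci:
        raise ValueError(
            f"genome too small for {n_loci} loci (placed {count}); "
            "increase chromosome lengths or reduce n_loci"
        )
    index, scores = [], []
    for locus in loci:
        for side in ("5p", "3p"):
            index.append(f"{locus.id}:{side}")
            if rng.random() < 0.5:
                scores.append(rng.uniform(-1.0, 0.0))
            else:
                scores.append(rng.uniform(0.5, 2.0))
    return loci, pd.Series(scores, index=index, name="invitro_score")


def generate_boundary_shifts(
    loci: Sequence[GenomicInterval],
    scores: pd.Series,
    genotypes: GenotypeMatrix,
    n_qtl: int = 20,
    effect_bp: float = 40.0,
    noise_sd_bp: float = 10.0,
    invitro_noise_gain: float = 1.0,
    cis_fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[dict[str, list[GenomicInterval]], TruthManifest]:
    """Per-strain region sets with planted boundary QTLs.

    ``n_qtl`` boundaries are chosen without replacement; a fraction
    ``cis_fraction`` gets the marker nearest the boundary (cis), the rest a
    random marker on another chromosome (trans). For a planted boundary,
    strain ``s`` shifts by ``sign * 2 * effect_bp * (1 - g)`` where ``g`` is
    its genotype at the planted marker; every boundary additionally gets
    Gaussian noise with sd ``noise_sd_bp * (1 + invitro_noise_gain *
    max(score, 0))``. Shifts that would invert a region are clipped and
    recorded in the manifest.
    """
    boundaries = [(f"{r.id}:{s}", r.id, s) for r in loci for s in ("5p", "3p")]
    if n_qtl > len(boundaries):
        raise ValueError("n_qtl exceeds the number of boundaries")
    if effect_bp < 0:
        raise ValueError("effect_bp must be >= 0")
    rng = np.random.default_rng(seed)
    strains = genotypes.strains
    n_strains = len(strains)
    spans = genotypes.spans
    gvals = genotypes.values

    planted_idx = rng.choice(len(boundaries), size=n_qtl, replace=False)
    n_cis = int(round(n_qtl * cis_fraction))
    manifest = TruthManifest(
        nucleosome_offsets={}, seeds={"boundary_shifts": seed if seed is not None else -1}
    )
    planted: dict[str, tuple[str, int, float]] = {}  # bid -> (marker, sign, effect)
    locus_by_id = {r.id: r for r in loci}
    for k, bi in enumerate(planted_idx):
        bid, rid, side = boundaries[bi]
        region = locus_by_id[rid]
        pos = region.start if side == "5p" else region.end
        kind = "cis" if k < n_cis else "trans"
        if kind == "cis":
            same = spans[spans["chrom"] == region.chrom]
            if same.empty:
                raise ValueError(f"no marker on chromosome {region.chrom}")
            marker = (same["start"] - pos).abs().idxmin()
        else:
            other = spans[spans["chrom"] != region.chrom]
            if other.empty:
                raise ValueError("trans QTL needs markers on another chromosome")
            marker = str(other.index[rng.integers(0, len(other))])
        sign = int(rng.choice([-1, 1]))
        planted[bid] = (str(marker), sign, float(effect_bp))
        manifest.planted_qtls.append(
            {
                "marker": str(marker),
                "trait": bid,
                "effect_bp": float(effect_bp),
                "kind": kind,
                "sign": sign,
            }
        )

    # per-boundary shift vectors across strains
    shift_vectors: dict[str, np.ndarray] = {}
    for bid, rid, side in boundaries:
        score = float(scores.get(bid, 0.0))
        sd = noise_sd_bp * (1.0 + invitro_noise_gain * max(score, 0.0))
        shifts = rng.normal(0.0, sd, size=n_strains) if sd > 0 else np.zeros(n_strains)
        if bid in planted:
            marker, sign, eff = planted[bid]
            g = gvals.loc[marker].to_numpy(dtype=float)
            shifts = shifts + sign * 2.0 * eff * (1.0 - g)
        shift_vectors[bid] = np.rint(shifts).astype(np.int64)

    strain_sets: dict[str, list[GenomicInterval]] = {s: [] for s in strains}
    for region in loci:
        d5 = shift_vectors[f"{region.id}:5p"]
        d3 = shift_vectors[f"{region.id}:3p"]
        for j, strain in enumerate(strains):
            start = max(0, region.start + int(d5[j]))
            end = region.end + int(d3[j])
            if start >= end:
                manifest.clipped.append(
                    {"region": region.id, "strain": strain, "start": start, "end": end}
                )
                mid = (start + end) // 2
                start, end = mid - 1, mid + 1
            strain_sets[strain].append(
                GenomicInterval(region.chrom, start, end, ".", region.id)
            )
    return strain_sets, manifest


def default_pattern_spec(
    nucleosome_offset_bp: int = 75,
    depth: int = 200,
    background_rate: float = 0.0,
) -> dict[str, dict]:
    """Per-assay track recipes: dyad placement and sampling parameters.

    Nucleosomal assays place dyads either just inside each boundary
    (``'boundary'``, at edge + offset) or at the region center
    (``'center'``); open-chromatin assays scatter cut sites uniformly inside
    the region. ``background_rate`` is in tags per bp of genome.
    """
    nuc = {
        "kind": "nucleosome",
        "dyad_sd": 20.0,
        "frag_len": 147,
        "tags_per_dyad": depth,
        "background_rate": background_rate,
    }
    return {
        "mnase": {**nuc, "dyads": "boundary", "offset": nucleosome_offset_bp},
        "h2az": {**nuc, "dyads": "center"},
        "h3k27ac": {**nuc, "dyads": "center"},
        "h3k4me1": {**nuc, "dyads": "boundary", "offset": nucleosome_offset_bp},
        "dhs": {"kind": "open", "tags_per_region": depth,
                "background_rate": background_rate},
        "faire": {"kind": "open", "tags_per_region": depth,
                  "background_rate": background_rate},
    }


def _nucleosome_tags(
    regions: Sequence[GenomicInterval],
    spec: dict,
    read_len: int,
    rng: np.random.Generator,
) -> list[Tag]:
    tags: list[Tag] = []
    frag = int(spec["frag_len"])
    sd = float(spec["dyad_sd"])
    n_per = int(spec["tags_per_dyad"])
    for region in regions:
        if spec["dyads"] == "boundary":
            off = int(spec["offset"])
            dyads = [region.start + off, region.end - off]
        elif spec["dyads"] == "center":
            dyads = [region.center]
        else:
            raise ValueError(f"unknown dyad placement {spec['dyads']!r}")
        for dyad in dyads:
            mids = dyad + rng.normal(0.0, sd, size=n_per)
            starts = np.rint(mids - frag / 2).astype(np.int64)
            minus = rng.random(n_per) < 0.5
            for s, m in zip(starts, minus):
                if m:
                    pos = max(0, int(s) + frag - read_len)
                    tags.append(Tag(region.chrom, pos, "-", read_len))
                else:
                    tags.append(Tag(region.chrom, max(0, int(s)), "+", read_len))
    return tags


def _open_tags(
    regions: Sequence[GenomicInterval],
    spec: dict,
    read_len: int,
    rng: np.random.Generator,
) -> list[Tag]:
    tags: list[Tag] = []
    n_per = int(spec["tags_per_region"])
    for region in regions:
        cuts = rng.integers(region.start, region.end, size=n_per)
        minus = rng.random(n_per) < 0.5
        for c, m in zip(cuts, minus):
            if m:
                # minus-strand 5' end (cut site) is the rightmost base
                pos = max(0, int(c) - read_len + 1)
                tags.append(Tag(region.chrom, pos, "-", read_len))
            else:
                tags.append(Tag(region.chrom, int(c), "+", read_len))
    return tags


def _background_tags(
    genome: Mapping[str, int], rate: float, read_len: int, rng: np.random.Generator
) -> list[Tag]:
    tags: list[Tag] = []
    if rate <= 0:
        return tags
    for chrom, length in genome.items():
        n = int(rng.poisson(rate * length))
        positions = rng.integers(0, max(1, length - read_len), size=n)
        strands = rng.random(n) < 0.5
        for p, m in zip(positions, strands):
            tags.append(Tag(chrom, int(p), "-" if m else "+", read_len))
    return tags


def generate_sequences(
    genome: Mapping[str, int],
    regions: Sequence[GenomicInterval],
    boundary_window: int = 147,
    cg_excess: float = 1.5,
    seed: int | None = None,
) -> dict[str, str]:
    """Genome sequence with elevated C/G dinucleotide frequency at boundaries.

    Background bases are iid uniform over ACGT (C/G-set dinucleotide
    frequency 0.25). In windows of ``boundary_window`` bp centered on each
    region boundary, per-base C/G probability is raised so that the iid
    C/G-set dinucleotide frequency becomes ``cg_excess * 0.25``.
    """
    if not (0 < cg_excess <= 4):
        raise ValueError("cg_excess must be in (0, 4]")
    rng = np.random.default_rng(seed)
    q = float(np.sqrt(0.25 * cg_excess))  # total per-base C+G probability
    boosted = np.array([(1 - q) / 2, q / 2, q / 2, (1 - q) / 2])
    alphabet = np.array(list("ACGT"))
    out: dict[str, str] = {}
    regions_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        regions_by_chrom.setdefault(r.chrom, []).append(r)
    half = boundary_window // 2
    for chrom, length in genome.items():
        codes = rng.integers(0, 4, size=length)
        for r in regions_by_chrom.get(chrom, []):
            for edge in (r.start, r.end):
                lo, hi = max(0, edge - half), min(length, edge + half + 1)
                codes[lo:hi] = rng.choice(4, size=hi - lo, p=boosted)
        out[chrom] = "".join(alphabet[codes])
    return out


def generate_tracks(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, int] | None = None,
    nucleosome_offset_bp: int = 75,
    pattern_spec: Mapping[str, dict] | None = None,
    depth: int = 200,
    read_len: int = 36,
    seed: int | None = None,
    with_sequence: bool = True,
) -> tuple[dict[str, list[Tag]], dict[str, str]]:
    """Sequencing-tag tracks per assay, plus planted genomic sequence.

    Nucleosomal assays (MNase, H2A.Z, marks) draw ``depth`` 147 bp fragments
    per planted dyad with Gaussian midpoint jitter and report ``read_len``
    bp reads from a random fragment end; open-chromatin assays (DHS, FAIRE)
    scatter cut sites uniformly inside regions. With zero background rate no
    tag falls outside the regions (beyond read length).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    genome = dict(genome or DEFAULT_GENOME)
    spec = dict(pattern_spec or default_pattern_spec(nucleosome_offset_bp, depth))
    seeds = _child_seeds(seed, len(spec) + 1)
    tracks: dict[str, list[Tag]] = {}
    for (assay, aspec), aseed in zip(sorted(spec.items()), seeds):
        rng = np.random.default_rng(aseed)
        if aspec["kind"] == "nucleosome":
            tags = _nucleosome_tags(regions, aspec, read_len, rng)
        elif aspec["kind"] == "open":
            tags = _open_tags(regions, aspec, read_len, rng)
        else:
            raise ValueError(f"unknown assay kind {aspec['kind']!r}")
        tags.extend(
            _background_tags(genome, float(aspec.get("background_rate", 0.0)),
                             read_len, rng)
        )
        tracks[assay] = tags
    sequences = (
        generate_sequences(genome, regions, seed=seeds[-1]) if with_sequence else {}
    )
    return tracks, sequences


def generate_genes(
    regions: Sequence[GenomicInterval],
    n_genes: int,
    tss_gap_range: tuple[int, int] = (50, 800),
    gene_length: int = 1_000,
    seed: int | None = None,
) -> tuple[list[GeneRecord], list[dict]]:
    """Genes with tss placed just outside a chosen region boundary.

    Each of ``n_genes`` distinct regions gets one gene whose tss sits
    ``tss_gap_range`` bp outside a randomly chosen boundary, transcribed
    away from the region. Returns the genes and the construction record
    (gene, region, facing side) — the geometric ground truth against which
    facing-boundary calls are scored.
    """
    if n_genes > len(regions):
        raise ValueError("n_genes exceeds the number of regions")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(regions), size=n_genes, replace=False)
    genes, facing = [], []
    for i, ri in enumerate(chosen):
        region = regions[int(ri)]
        gap = int(rng.integers(tss_gap_range[0], tss_gap_range[1] + 1))
        side = "5p" if rng.random() < 0.5 else "3p"
        gid = f"G{i + 1:04d}"
        if side == "5p":
            tss = region.start - gap
            start, end, strand = tss - gene_length + 1, tss + 1, "-"
        else:
            tss = region.end + gap
            start, end, strand = tss, tss + gene_length, "+"
        if start < 0:
            continue
        genes.append(GeneRecord(gid, region.chrom, tss, strand, start, end))
        facing.append({"gene": gid, "region": region.id, "side": side})
    return genes, facing


def generate_expression(
    genes: Sequence[GeneRecord],
    regions: Sequence[GenomicInterval],
    traits: BoundaryTraitMatrix,
    genotypes: GenotypeMatrix,
    target_r: float = 0.6,
    noise_sd: float = 1.0,
    seed: int | None = None,
    facing: Sequence[dict] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Expression matrix with planted boundary-distance correlations.

    Genes whose facing boundary is a retained trait get expression
    ``sign(target_r) * trait + noise`` with the noise sd calibrated from the
    trait's sample sd so the population correlation equals ``target_r``;
    all other genes are pure Gaussian noise with sd ``noise_sd``. The
    ``facing`` construction records from :func:`generate_genes` define which
    boundary each gene faces; without them the facing side is derived
    geometrically.
    """
    if not (-1 <= target_r <= 1):
        raise ValueError("target_r must be in [-1, 1]")
    if abs(target_r) == 1 and noise_sd > 0:
        raise ValueError("target_r of +/-1 is inconsistent with noise_sd > 0")
    rng = np.random.default_rng(seed)
    strains = traits.strains
    region_by_id = {r.id: r for r in regions}
    facing_map: dict[str, tuple[str, str]] = {}
    if facing is not None:
        facing_map = {f["gene"]: (f["region"], f["side"]) for f in facing}
    else:
        for gene in genes:
            for rid, region in region_by_id.items():
                side = tss_facing_boundary(region, gene)
                if side is not None:
                    facing_map[gene.id] = (rid, side)
                    break
    rows, entries = [], []
    for gene in genes:
        hit = facing_map.get(gene.id)
        trait_id = f"{hit[0]}:{hit[1]}" if hit else None
        planted = (
            trait_id is not None
            and trait_id in traits.values.index
            and target_r != 0
        )
        if planted:
            t = traits.values.loc[trait_id, strains].to_numpy(dtype=float)
            sd_t = t.std()
            if sd_t == 0:
                planted = False
        if planted:
            sign = 1.0 if target_r > 0 else -1.0
            r = abs(target_r)
            noise = (
                rng.normal(0.0, sd_t * np.sqrt(1 - r**2) / r, size=len(strains))
                if r < 1
                else np.zeros(len(strains))
            )
            rows.append(sign * t + noise)
            entries.append(
                {
                    "gene": gene.id,
                    "region": hit[0],
                    "side": hit[1],
                    "trait": trait_id,
                    "target_r": float(target_r),
                }
            )
        else:
            rows.append(rng.normal(0.0, noise_sd, size=len(strains)))
    expr = pd.DataFrame(rows, index=[g.id for g in genes], columns=strains)
    return expr, entries


DEFAULT_CONFIG: dict = {
    "n_strains": 96,
    "chrom_lengths": None,  # DEFAULT_GENOME
    "marker_spacing": 5_000,
    "recomb_prob": 0.02,
    "missing_rate": 0.02,
    "n_loci": 100,
    "width_range": (300, 800),
    "min_gap": 1_000,
    "n_qtl": 20,
    "effect_bp": 40.0,
    "noise_sd_bp": 10.0,
    "invitro_noise_gain": 1.0,
    "cis_fraction": 0.5,
    "nucleosome_offset_bp": 75,
    "depth": 200,
    "read_len": 36,
    "n_genes": 30,
    "target_r": 0.6,
    "expression_noise_sd": 1.0,
    "trait_cutoff": 150.0,
}


def simulate_study(
    config: Mapping | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Generate a complete synthetic study; optionally write it to disk.

    Returns a dict with the in-memory objects (genotypes, loci, scores,
    strain region sets, traits, tracks, sequences, genes, expression,
    manifest). With ``out_dir`` set, writes genotype/expression TSVs,
    reference and per-strain BEDs, per-assay tag BEDs, FASTA, gene BED and
    the JSON truth manifest.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    genome = dict(cfg["chrom_lengths"] or DEFAULT_GENOME)
    s_cross, s_loci, s_shift, s_track, s_gene, s_expr = _child_seeds(seed, 6)

    genotypes = generate_cross(
        cfg["n_strains"], genome, cfg["marker_spacing"], cfg["recomb_prob"],
        cfg["missing_rate"], s_cross,
    )
    loci, scores = generate_loci(
        cfg["n_loci"], tuple(cfg["width_range"]), genome, cfg["min_gap"], s_loci
    )
    strain_sets, manifest = generate_boundary_shifts(
        loci, scores, genotypes, cfg["n_qtl"], cfg["effect_bp"],
        cfg["noise_sd_bp"], cfg["invitro_noise_gain"], cfg["cis_fraction"], s_shift,
    )
    tracks, sequences = generate_tracks(
        loci, genome, cfg["nucleosome_offset_bp"], None, cfg["depth"],
        cfg["read_len"], s_track,
    )
    traits = build_boundary_traits(loci, strain_sets, cfg["trait_cutoff"])
    genes, facing = generate_genes(loci, cfg["n_genes"], seed=s_gene)
    expression, expr_entries = generate_expression(
        genes, loci, traits, genotypes, cfg["target_r"],
        cfg["expression_noise_sd"], s_expr, facing,
    )
    manifest.nucleosome_offsets = {"mnase": cfg["nucleosome_offset_bp"],
                                   "h3k4me1": cfg["nucleosome_offset_bp"]}
    manifest.expression_effects = expr_entries
    manifest.seeds.update(
        {"root": seed if seed is not None else -1, "cross": s_cross, "loci": s_loci,
         "shifts": s_shift, "tracks": s_track, "genes": s_gene, "expression": s_expr}
    )

    study = {
        "config": cfg,
        "genome": genome,
        "genotypes": genotypes,
        "loci": loci,
        "scores": scores,
        "strain_sets": strain_sets,
        "traits": traits,
        "tracks": tracks,
        "sequences": sequences,
        "genes": genes,
        "expression": expression,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    genotypes: GenotypeMatrix = study["genotypes"]
    cbio.write_matrix(genotypes.values, out / "genotypes.tsv")
    cbio.write_bed(
        [
            GenomicInterval(r.chrom, r.start, r.end, ".", str(m))
            for m, r in study["genotypes"].spans.iterrows()
        ],
        out / "markers.bed",
    )
    cbio.write_bed(study["loci"], out / "reference_loci.bed")
    study["scores"].to_csv(out / "boundary_scores.tsv", sep="\t", header=True)
    strains_dir = out / "strains"
    strains_dir.mkdir(exist_ok=True)
    for strain, regions in study["strain_sets"].items():
        cbio.write_bed(regions, strains_dir / f"{strain}.bed")
    traits: BoundaryTraitMatrix = study["traits"]
    cbio.write_matrix(traits.values, out / "boundary_traits.tsv")
    traits.positions.to_csv(out / "boundary_positions.tsv", sep="\t")
    for assay, tags in study["tracks"].items():
        cbio.write_tags(tags, out / f"tags_{assay}.bed")
    if study["sequences"]:
        cbio.write_fasta(study["sequences"], out / "genome.fasta")
    cbio.write_bed(
        [
            GenomicInterval(g.chrom, g.start, g.end, g.strand, g.id)
            for g in study["genes"]
        ],
        out / "genes.bed",
    )
    pd.DataFrame(
        [(g.id, g.chrom, g.tss, g.strand) for g in study["genes"]],
        columns=["id", "chrom", "tss", "strand"],
    ).to_csv(out / "gene_tss.tsv", sep="\t", index=False)
    cbio.write_matrix(study["expression"], out / "expression.tsv")
    study["manifest"].to_json(out / "manifest.json")
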