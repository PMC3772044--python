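# Methods

This note documents the models, conventions and design choices behind
`chromborder`: what each stage computes, which parameters matter and why
their defaults are what they are, what the synthetic-study generator does
and does not emulate, and the numerical details (tie-breaks, degenerate
inputs, tolerances) that determine exact outputs.

## Coordinates and primitive types

All coordinates are 0-based half-open (BED convention); 1-based inputs are
converted at I/O boundaries only. A *tag* is one mapped read (leftmost
base, strand, length). When a read must be reduced to one base pair — DNase
cut sites — the convention is the read's 5′ end: leftmost base on the plus
strand, rightmost on the minus strand, because DNase cut sites are read 5′
ends. Read extension to a fixed length T acts from the 5′ end: a plus read
at p becomes [p, p+T), a minus read with leftmost p and length L becomes
[p+L−T, p+L), clipped at zero. Extension defaults are assay-specific:
147 bp (one nucleosome footprint) for MNase/nucleosome tags, 200 bp for
histone ChIP, none (cut-site points) for DHS. Nearest-feature queries break
distance ties toward the smaller coordinate so all outputs are
deterministic; queries against another chromosome return "no hit" rather
than raising, which simplifies batch calls.

## Peak-end refinement

Open-chromatin peaks called from enrichment data tend to have imprecise
ends. The refinement procedure anchors them against DNase cut sites: the
expected outside count E is the mean, over all peaks and both sides, of
cut sites in the `flank_w` window just outside the original boundary; each
side is then extended outward by the minimal Δ ∈ [0, `max_extend`] such
that the window just outside the new boundary holds ≤ E cut sites.
Refinement is extension-only — extension strictly reduces outside counts
and cannot collapse a peak, whereas a shrink rule has no analogous
stopping criterion. E is a single scalar pooled over both sides of all
peaks. `flank_w` (200 bp) and `max_extend` (500 bp) are exposed
parameters: the window width and a cap on adjustment are method choices,
and a side that cannot be satisfied within the cap is clipped there and
flagged `satisfied=False`. The left end never extends below coordinate 0.

## TF-peak summit filter

ChIP tags are assigned to a peak when their full footprint overlaps it;
the summit is the base with maximal footprint coverage (leftmost on ties);
a peak is kept when the fraction of its tags covering the summit is at
least `min_frac` (default 0.8). This selects peaks likely to contain a
single focused binding site. Peaks with zero tags are dropped from the
output entirely rather than reported with an undefined fraction.

## Meta-profiles

*Anchored profiles* average per-base coverage of (optionally extended)
tags over a ±window around a set of anchors; minus-strand anchors mirror
the offset axis so positive offsets always point the same biological way.
The helper `boundary_anchors` orients both edges of a region with positive
offsets pointing into the interior.

*Binned body profiles* rescale regions of different widths onto a common
axis: the body is split into `n_bins` (default 10) equal-width bins — with
fractional bin edges when the width does not divide evenly — and each
flank into fixed 100-bp bins over 1 kb. A tag contributes its bp overlap
to each bin; the reported value is the mean over regions of overlap-bp per
bin-bp, i.e. a per-base density, which is what makes bodies of different
widths comparable. Mass is conserved: summing value × bin width × region
count recovers total overlapped bp (exactly, for equal-width regions).
Regions are treated as unstranded; no orientation flip is applied.

*Dinucleotide profiles* report, per position of an aligned sequence set,
the fraction of sequences whose dinucleotide belongs to the C/G set
{CC, CG, GC, GG} or A/T set {AA, AT, TA, TT}, divided by a background set
frequency (from supplied background sequences, else the window mean).
N-containing dinucleotides are excluded from numerator and denominator.

*H2A.Z enrichment*: per-nucleosome mark level is the count of overlapping
mark-tag footprints (raw counts, not length-normalized). Enrichment of a
mark is the mean level over nucleosomes that intersect a called H2A.Z
nucleosome (any overlap) divided by the mean over all nucleosomes;
association with H2A.Z is the Spearman correlation between per-nucleosome
H2A.Z tag count and mark level. A mark with identical level on every
nucleosome has no rank information; its correlation is reported as 0 by
convention, and a mark with zero overall mean has undefined enrichment
(NaN).

## Cross-strain boundary variation

Homologous regions are mapped by nearest same-kind anchor (5′ end,
floored center, or 3′ end) within a search radius of 500 bp; distances are
signed (strain − reference), with NaN as the beyond-radius sentinel.
Overlap-frequency curves count, per reference locus, the strains matching
within each grid distance — cumulatively or per right-closed bin — and
loci carrying any sentinel are excluded from mean curves with their count
reported. Score stratification cuts at in vitro occupancy score 0 and 0.5
with strict inequalities (0.5 is the positioned-nucleosome threshold;
boundary values fall in the middle stratum).

The *boundary trait matrix* takes both ends of each reference region as
independent candidate trait loci; the trait value is the unsigned nearest
same-side end-to-end distance per strain, and a locus is retained only
when that distance is strictly below the cutoff (default 100 bp) in
*every* strain. Unsigned distances are the trait definition; signed
distances remain available in the homolog distance matrix for
heat-map-style summaries. The shuffle control relocates every strain
region uniformly within its chromosome (width preserved, overlaps
allowed) and recomputes nearest center-to-center and end-to-end
distances, giving the null distribution against which the observed
clustering of homologs is judged.

## QTL mapping

Adjacent markers whose genotypes differ in at most `max_mismatch` (2)
strains — ignoring strains missing in either marker — are chained greedily
left-to-right and collapsed to per-strain means (fractional values are
expected on merged markers). The association statistic is
|Pearson r| between the numeric genotype row (0/0.5/1) and the trait row;
the 0.5 coding places missing genotypes at the uninformative midpoint.
Zero-variance rows yield statistic 0 with a degenerate flag.

Significance comes from strain-label permutations: each iteration permutes
the columns of the whole trait matrix once, preserving inter-trait
correlation, and recomputes all statistics. Two null conventions are
provided:

* **per-pair** (default): p = (1 + #{A\* ≥ A}) / (N + 1) from the pair's
  own N permuted replicates. The +1 pseudocount guarantees p > 0 and the
  minimum attainable p is 1/(N+1).
* **pooled**: the count runs over the permuted statistics of *all* pairs,
  so the minimum attainable p is 1/(N·n_pairs + 1).

The choice matters for genome-scale scans: with N = 1000 and tens of
thousands of pairs, the per-pair minimum p (~10⁻³) can never clear a
Benjamini–Hochberg threshold of 0.01 — BH would need roughly n_pairs/100
pairs at the minimum. The pooled null resolves small enough p values from
the same permutation budget, and the recovery analyses here use it; the
per-pair null remains the default and is what the calibration analysis
exercises. FDR is BH step-up over all pairs in both cases. The default
permutation count is 1000, configurable.

Associations are *cis* when marker span and boundary position share a
chromosome with a gap ≤ 100 kb (boundaries inside the span have gap 0; the
boundary case gap = 100 kb is cis), else *trans*. Hotspots are markers
with strictly more than `min_links` (5) trans associations at the chosen
FDR. Candidate genes are those overlapping the marker span padded by
10 kb on each side, optionally intersected with a keyword gene list.

The surface is a statsmodels-style pair: `BoundaryQTL(genotypes, traits)`
holds the aligned data; `fit(n_perm, seed, null)` returns
`BoundaryQTLResults` carrying the statistic matrix, tidy records with p,
FDR and class, and `significant() / hotspots() / candidate_genes() /
summary()` accessors.

## Expression linkage

A gene participates when its tss lies within 1 kb of a region (distance 0
inside). The facing boundary is the region end whose coordinate is nearer
the tss, with equidistant ties going to 5′ — the natural geometric reading
of "facing". Genotype-group comparisons split strains at genotype 0 vs 1
(0.5 excluded) and use the Wilcoxon rank-sum test with tie-corrected
normal approximation, preferred over a t-test because boundary distances
are bounded and non-Gaussian. Distance-expression correlation is Pearson
by default (Spearman available), with pairwise deletion of missing
strains and NaN for zero-variance inputs. `dual_qtl_overlap` reports
bidirectional key-set overlap fractions between two record sets.

## The synthetic-study generator

The generator defines the study conditions the tests and the acceptance
analyses run under; its defaults are fixed once:

| parameter | default | rationale |
| --- | --- | --- |
| strains | 96 | the cross size the design emulates |
| genome | 10 chromosomes × 150 kb | desk-scale stand-in for a small eukaryotic genome |
| marker spacing | 5 kb | ~300 markers genome-wide |
| recombination / interval | 0.02 | a few cM between adjacent markers |
| missing genotype rate | 0.02 | typical residual missingness |
| loci | 100, widths 300–800 bp, gaps ≥ 1 kb | non-overlapping accessible regions |
| boundary score mixture | half U[−1, 0), half U(0.5, 2] | clearly separated low/high occupancy strata |
| planted QTLs | 20, effect 40 bp, noise sd 10 bp | 80 bp group separation against 10 bp noise |
| cis fraction | 0.5 | equal representation of both architecture classes for testing |
| score-noise gain | 1.0 (linear) | the coupling strength is not derivable from data; exposed as a parameter |
| nucleosome offset | 75 bp inside each edge | the boundary-nucleosome geometry |
| fragment/read length | 147 / 36 bp | mononucleosome footprint, short single-end reads |
| depth | 200 tags per nucleosome / region | enough to localize dyads to a few bp |
| boundary C/G excess | 1.5× in 147 bp windows | a plantable, checkable sequence signal |
| expression target r | 0.6 | a strong but noisy facing-boundary correlation |

Genotypes are a two-state Markov chain per strain and chromosome (first
marker fair, flip probability = recombination probability), on the
{0, 0.5, 1} scale from the start so the association stage consumes them
unchanged.

Planted boundary effects are **anchored at the BY allele**: strain
boundaries sit at the reference when the genotype at the planted marker is
1, at sign·2·effect bp when it is 0, and midway when missing. The
group-mean position difference is 2·effect either way, but anchoring is
what keeps the *unsigned* end-to-end trait informative — it mirrors the
real design, where the reference strain is itself the BY parent of the
cross. A symmetric parameterization (±effect around the reference) would
put both homozygous classes at the same unsigned distance and erase the
signal from the trait as defined. One marker per planted QTL; cis QTLs use
the marker nearest the boundary, trans QTLs a random marker on another
chromosome. Boundary noise sd is `noise_sd · (1 + gain · max(score, 0))`,
so positive in vitro scores inflate positional variance linearly — the
magnitude of this coupling is a free parameter, not an estimated one.
Shifts that would invert a region are clipped and logged in the manifest.

Tracks: nucleosomal assays draw 147 bp fragments per planted dyad
(boundary dyads at edge + 75 bp for MNase and H3K4me1, central dyads for
H2A.Z and H3K27ac) with Gaussian midpoint jitter (sd 20 bp) and report a
36 bp read from a random fragment end; DHS/FAIRE scatter cut sites
uniformly inside regions. With zero background rate no tag falls outside
the regions. Sequence is iid uniform ACGT except in 147 bp
boundary-centered windows, where the per-base C+G probability is raised to
√(0.25 · excess) so the iid C/G-set dinucleotide frequency becomes
excess × 0.25.

Expression for a planted gene is sign(r)·trait + Gaussian noise with sd
σ_t·√(1−r²)/|r| calibrated from the trait's sample sd, giving population
correlation r; other genes are pure noise. Gene tss positions are placed
50–800 bp outside a randomly chosen boundary, transcribed away from the
region, and the construction side is recorded in the manifest — the
geometric ground truth the analysis-side facing-boundary call is scored
against, kept separate from that call on purpose.

What the generator does **not** emulate: read errors and mappability,
diploid genetics or segregation distortion, overlapping or nested
regions, inter-locus spacing structure, realistic expression
distributions, and any coupling between chromatin accessibility level and
boundary position. Tests passing on this generator therefore demonstrate
correctness of the procedures and recoverability of planted effects under
clean conditions, not performance on real sequencing data.

## Analysis problem sizes and parameter choices in the recovery analyses

The calibration analysis uses a QTL-free cross (96 strains, 300 raw
markers, 200 boundary traits, 500 permutations, per-pair null): the
fraction of pairs at p ≤ 0.05 should sit within Monte-Carlo error of 0.05
and essentially nothing should clear FDR 0.01.

The recovery analysis plants 20 QTLs (80 bp separation, 10 bp noise,
score-noise gain 0 so the noise sd is exactly 10 bp), merges markers,
and scans with 1000 permutations and the pooled null. Two analysis
parameters deviate from the single-study defaults, both fixed from the
experimental design rather than tuned: the trait-retention cutoff is
150 bp instead of 100 bp, because the planted displacement (80 bp) plus
four noise sds (40 bp) exceeds 100 bp and the all-strain filter would
otherwise censor most planted boundaries by construction; and the pooled
null is used for the reason given above. Recovery credits a planted
marker when the trait is significant at FDR 0.01 with any merged marker
whose span lies within 20 kb of the planted marker (marker merging makes
the merged span, not a point, the natural unit). Planted cis/trans labels
are checked against `classify_associations` on the planted pairs
directly.

Other analyses: the boundary-nucleosome check reads the interior maximum
of the boundary-anchored MNase profile (40 loci, depth 200, window
300 bp) and expects it within ±5 bp of +75; the score-variance check uses
560 boundaries with gain 2 and a one-sided rank-sum test between the
score > 0.5 and score < 0 strata; the expression check requires the mean
recovered facing-boundary correlation within ±0.15 of the planted 0.6 and
the facing side identified for every planted gene.

## Known limitations

* Peak refinement never shrinks peaks; peaks over-called outward stay
  over-called.
* The permutation scan treats markers as independent tests under BH;
  linkage makes neighbouring markers' p values correlated, so significant
  pairs cluster around true QTLs and pair counts exceed QTL counts.
* `merge_markers` compares each marker to its immediate raw predecessor
  only (the chaining rule), so slow genotype drift along a chain can
  accumulate more than `max_mismatch` total differences.
* The homolog search radius (500 bp) and the trait cutoff interact: loci
  whose true homolog moved beyond the radius are sentinels, not large
  distances.
* `shuffle_control` does not enforce non-overlap among relocated regions.
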