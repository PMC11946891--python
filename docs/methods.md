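# Methods

This note documents the models, statistics and numerical choices behind
perturbkit's three analysis stages and its synthetic-data generators, in
the order data flows through the pipeline.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure each downstream stage
assumes*, with explicit ground truth, so that recovery and calibration can
be measured. They do not attempt biological realism beyond that.

**Pooled screen** (`simulate_screen`). A library of `n_genes ×
guides_per_gene` targeting guides plus nontargeting controls receives
log-normal baseline abundances (σ_log default 0.5, a typical 10–90%
library skew of ~3.5-fold). Planted selection acts *multiplicatively on
pre-sampling abundance* per (gene, organ, treatment), after which
per-sample abundances are renormalized — selection changes composition,
as in a real pool. Counts are negative binomial with variance
μ + φμ², φ default 0.2, matching common pooled-screen overdispersion;
φ = 0 falls back to Poisson. The default design has three T0 reference
replicates and four conditions × three replicates (tumour IgG, tumour /
lung / liver anti-PD-1), batched by organ, at 10⁶ reads per sample
(~10³ reads per guide). Not modelled: PCR/sequencing error, guide
efficiency variation, copy-number effects, paired T0/Tend variance.

**CROP-seq** (`simulate_cropseq`). Every cell carries one true guide with
Poisson(30) capture UMIs over an ambient Poisson(0.2) background on every
other guide; a 3% doublet fraction carries a second true guide, flagged
only in the truth object so assignment must discover it. Cluster labels
are categorical draws from the cell's gene-specific probability vector:
base probabilities (default uniform over 6 clusters) times exp(shift),
renormalized. Doublets draw their label from the first guide's gene (a
dominant-phenotype simplification). Per-cell totals are log-normal
(median 10⁴ UMIs, σ 0.4) and mitochondrial fractions Beta(2, 38)
(mean 5%, ~2% mass above the 10% QC cut). The transcriptome itself is not
simulated; clustering tests build small expression matrices directly.

**Localization fields** (`simulate_localizations`). Homogeneous Poisson
background in a rectangular ROI plus uniform discs. The default field —
10×10 µm, 2,000 background points, three discs of 40 points at radius
250 nm (≈10× the average density) — is the reference condition for the
clustering benchmarks; truth labels each point background or disc index.

All generators draw from per-stage streams spawned deterministically from
one seed and are bit-reproducible.

## Screen enrichment

**Sample QC** drops samples whose total count is below `min_total_fraction`
(default 0.1) of the median sample total, mirroring the exclusion of
failed libraries.

**Normalization** uses nontargeting median-of-ratios: per-guide geometric
means across samples form the reference; a sample's size factor is the
median NT count/reference ratio (NT guides with any zero count are
excluded from the median, as usual for median-of-ratios). By construction
the median normalized NT ratio is exactly 1 per sample. LFC is computed
against the mean normalized T0 with pseudocount 0.5 added to both sides.
*Caveat:* because the geometric-mean reference includes every sample,
rescaling one sample's raw counts moves all normalized counts by a common
factor c^(1/S); the LFC is exactly invariant to this only at pseudocount
0 (at the default 0.5 the residual is ~10⁻⁴ log2 units at typical depth).

**Batch adjustment** is a per-guide location–scale transform: within batch
b, x′ = (x − m_gb)·(s_g/s_gb) + m_g, with scaling skipped for batches of
fewer than 3 samples or zero within-batch SD. This is a deliberate,
simplified stand-in for empirical-Bayes batch correction; it has no
shrinkage. **Important caveat:** when batch labels coincide with the
biological contrast (here, organ), centering per batch absorbs the
condition signal — in that design the adjustment must be disabled
(`batch_adjust: false`), and the benchmark pipelines do so. It is intended
for designs where batches are orthogonal to the contrasts of interest.

**Rank score.** Guides are ranked by mean LFC over a condition's
replicates among all N library guides (descending for enrichment;
ties broken lexically by guide id). For a gene's sorted ranks r₁<…<r_k the
score is max_j −log10 P[Binom(k, r_j/N) ≥ j] over ranks within the top
fraction (default 0.10, configurable); genes with no guide in the top
fraction score 0. The p-value is a permutation tail
(1 + #{null ≥ obs})/(n_perm + 1), where the null redraws k ranks uniformly
without replacement; since the null law depends only on (k, N) it is
computed once per guide-count k — an exact sharing, not an approximation.

**Effect score.** The gene effect is the mean guide LFC; its two-sided
p-value compares |effect − μ₀| (μ₀ = mean NT LFC) against a resampling
null with two refinements that measurement showed to be necessary at
desk-scale control counts (tens of NT guides):

1. *Variance stabilization.* The raw NT pool's spread is an unstable width
   estimate at n≈25 (observed sd 0.35–0.79 around a true 0.55 across
   simulated conditions), which produces bursts of false positives when it
   lands low. NT deviations are rescaled so their SD matches the robust
   (MAD-based) spread of *all* guides in the condition — robust on the
   all-guide side because hits live there, plain SD on the control side
   because it is null by construction. The scale step is skipped when
   either spread is zero, which preserves exact behaviour on degenerate
   inputs (an all-zero NT pool gives p = 1/(n_resample+1) for any real
   effect).
2. *Centre uncertainty.* Each null draw is the deviation of a k-guide
   resample mean from an independent bootstrap mean of the whole control
   pool, so the null carries the same μ₀ estimation error as the observed
   contrast (without this the mid-range p-value CDF ran ~6% above uniform).

With both, the null p-values are statistically indistinguishable from
uniform (their mean sup-deviation from the diagonal matches the
theoretical value for exact uniformity at 200 genes). BH adjustment is
applied within condition. The distillation rule requires, per the study's
dual-algorithm intersection, rank p ≤ 0.05 **and** effect FDR ≤ 0.05 with
enriched direction, in the *same* condition (the stricter reading);
hits supported in more than one organ are flagged multi-site, and
`tissue_distribution` reports per-organ counts and the multi-site
fraction (0 with an `undefined` flag when there are no hits).

## CROP-seq ranking

**Assignment.** A guide is dominant when its UMIs are ≥ `min_umi`
(default 3) and ≥ `dominance` (default 3.0) times the runner-up; at most
one guide can dominate. Cells with no guide at the floor are NONE; cells
with guides at the floor but no dominant guide are MULTIPLE; both are
excluded downstream. A per-guide knee detector was considered and
rejected as unstable at small cell counts.

**QC.** Per sample, cells outside the [0.01, 0.99] quantiles of total
UMIs are removed (doublet/dropout proxy; cutoffs are per-sample because
depth differs between samples); then cells with mitochondrial fraction
strictly greater than 0.10 are removed (a cell at exactly 10% is kept).
Samples with fewer than 10 cells skip the quantile filter with a warning.

**Clustering stand-in.** Depth-normalize to 10⁴, log1p, per-gene unit
scaling clipped at ±10, PCA to 15 components, k-nearest-neighbour graph
(k = 15), Leiden at resolution 0.3, deterministic under a fixed seed.
This intentionally omits batch integration and cell-cycle regression;
externally provided cluster labels are always accepted instead, and the
simulator emits truth-derived labels for exactly that use.

**Per-cluster enrichment.** For gene g and cluster c the 2×2 table of
(g cells, NT cells) × (in c, not in c) gives a Haldane-corrected odds
ratio (+0.5 on all four cells, for the OR only, keeping degenerate tables
finite) and a two-sided Fisher exact p on the raw table.

**Combined rank.** Within each cluster genes are ranked by descending OR
(ties: ascending p, then gene name). The signed score sums rank
percentiles pct = 1 − (rank−1)/(G−1) over positive clusters minus negative
clusters; percentiles rather than raw ranks make scores invariant to the
gene-set size (raw-rank summation is available behind a flag). Clusters
assigned to neither role contribute nothing, matching a seven-cluster
analysis that weights only clusters 0–5. A known statistical limitation,
confirmed by simulation: with ~20 genes and ~150 cells per gene, a
phenotype concentrated in one positive cluster (e.g. cluster-4 probability
×2, cluster-0 ×0.5) shifts the combined score by less than the spread of
the best null gene's percentile sum, so reaching combined rank 1 is
unreliable at that effect size — the benchmark script reports the measured
top-rank seed fraction for exactly this setting.

## Voronoi SMLM clustering

**Tessellation.** scipy's Voronoi diagram with eight ghost points on a
circle of 100× the ROI extent, which closes all real cells; bisectors to
ghosts lie far outside the ROI, so the ROI-clipped cells are exact. Cells
are clipped with shapely; clipped areas partition the ROI (relative 10⁻⁶
checked in tests). Duplicate coordinates are jittered by 10⁻⁶ nm with a
fixed internal seed and a warning; an all-collinear point set is an
error. Adjacency connects points whose clipped cells share a boundary of
positive length: ridges between two interior (unclipped) cells are
adjacent by construction; boundary cells are checked geometrically.

**Selection and grouping.** Average density is defined globally as
N/|ROI| (the mean of per-point densities is biased upward by small cells
and available only as an option); a point is selected when its density
exceeds `factor` × average (default 3). The threshold is relative, so
selection is invariant to uniform coordinate scaling. Connected components
of selected cells are retained when they hold strictly more than
`min_cluster_size` localizations (default 10: a 10-point component is
discarded, an 11-point one kept). Points on the ROI boundary are eligible
for selection by default (exclusion is an option).

**Summaries.** The primary clustered fraction is clustered/total per ROI.
The literal mean per-cluster fraction mean_k(n_k)/Σ_k n_k is also emitted
for fidelity, with the caveat that it equals 1/K whenever K clusters are
retained and is therefore degenerate as a comparison metric. Densities are
reported per nm² and per µm²; coordinates are assumed to be nm throughout
(pixel-size handling is an upstream concern).

## Pipeline and reproducibility

All tabular outputs are TSV with a header comment carrying the tool
version and configuration hash; the hash covers the seed and stage
parameters only, so identical computations land identical bytes regardless
of output location. Each run writes a resolved configuration copy and a
manifest with input/output SHA-256 hashes and per-stage record counts;
reruns with an unchanged configuration skip stages whose recorded outputs
are present and hash-identical. One global seed spawns per-stage streams;
all randomness flows through numpy Generators.

## Benchmark problem sizes

The benchmark script and acceptance tests use 200 genes × 5 guides with
25 NT controls and 4 conditions × 3 replicates for the screen stage
(n_perm = 1000, n_resample = 10,000), 20 genes × 150 cells plus 500 NT
cells for CROP-seq, and 2,120-point fields for the SMLM stage — sizes
chosen so every recovery and calibration property is measurable with
tight Monte-Carlo error on a single CPU in seconds.

## What passing tests do and do not show

The simulators match the distributional assumptions of the methods by
construction, so green benchmarks demonstrate internal correctness and
statistical calibration — not robustness to real-data pathologies such as
guide-efficiency heterogeneity, ambient RNA contamination structure,
batch effects orthogonal to the recorded labels, or localization drift
and multi-blinking, none of which are modelled.
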