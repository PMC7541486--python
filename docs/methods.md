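# Methods

`episcope` quantifies how strongly each transcriptomic neuronal subtype in a
case/control single-nucleus RNA-seq cohort is affected by the disease
condition, and identifies condition-associated co-expression programs. This
note records the statistical procedures, their assumptions, the tunable
parameters, and the design decisions taken where the methodology left choices
open.

## The expression-similarity score

The central per-subtype statistic asks: *are a subtype's case transcriptomes
farther from the controls than the controls are from each other?*

1. All cells (both conditions) are total-count normalized (default scale
   10,000 per cell, no log transform) and decomposed jointly by PCA into 100
   components (fewer when rank-limited). Fitting the PCA jointly on both
   conditions is essential: centroids of the two conditions must live in a
   common space.
2. For each subtype *t* and sample *s* with at least `min_cells` (default 5)
   cells, the centroid v̄(t, s) is the arithmetic mean of the cells' PC
   scores.
3. All pairwise Pearson correlations c(t, sᵢ, sⱼ) between a subtype's sample
   centroids are computed over the PC coordinates (not over genes).
4. The control–control correlations give a robust baseline: m(t) is their
   40% trimmed mean (trimming 40% from *each* tail, the convention of
   `scipy.stats.trim_mean` and R's `mean(x, trim=)`; with fewer than one
   value left the median is used) and σ(t) their median absolute deviation
   scaled by 1.4826 for consistency with the normal (the default of R's
   `mad`; the constant is a config switch).
5. Every (control, case) sample pair is scored z = (c − m)/σ. Unaffected
   subtypes score near 0; condition-shifted subtypes score negative. Subtypes
   with σ = 0 are flagged degenerate and excluded.

The per-subtype score distribution (median and quartiles over all
control–case pairs) is reduced to an ordinal category: **affected** when the
upper quartile is below 0, **highly affected** when additionally the median
falls below the class's median-of-medians, and exactly one **top-1** per
class (principal neurons and interneurons separately), the subtype with the
lowest median. Ties break deterministically by subtype name.

Assumptions: at least 3 control samples per subtype (else no baseline), and
enough cells per (subtype, sample) group that centroid noise is small
relative to cross-sample variation. The score is invariant to subtype
relabeling, sample order, and PCA sign conventions (signs are fixed by
making each component's largest-magnitude loading positive).

## Pseudobulk differential expression

Counts are summed per (sample, gene) within each subtype and tested with a
negative-binomial GLM per gene — median-of-ratios size factors, trended
dispersion shrinkage and a Wald test, i.e. the DESeq2 procedure, provided by
`pydeseq2`. The sample, not the cell, is the replication unit; at least two
samples per condition are required. DE genes are those with |Wald Z| > 3
(strict) that are also *expressed*: raw count above 1 UMI in at least 5% of
the subtype's cells. The expressed-gene union across subtypes is the
background universe for all enrichment tests. BH-adjusted p-values are
reported per subtype but the headline filter is on Z.

Gene-list enrichment (curated epilepsy genes, GWAS genes) uses Fisher's
exact test on the 2×2 table (DE ∩ list vs background), with the effect size
h estimated as the conditional maximum-likelihood odds ratio and an exact
95% CI from inverting the conditional test (both via
`scipy.stats.contingency.odds_ratio`; cross-checked in the tests against a
brute-force likelihood scan). Categories: h > 1 affected, CI lower bound > 1
highly affected, largest h per class top-1; an undefined h (empty margins)
ranks 0 with a flag.

Two count metrics are adjusted for their known covariates by robust linear
regression (Huber M-estimation, tuning constant 1.345, IRLS to 1e-8): the
number of DE genes regressed on the number of cells, and the number of
enriched GO terms regressed on the number of DE genes. Positive residuals
mark affected subtypes; residuals above the 75th percentile (linear
interpolation) of the affected set mark highly affected; the class maximum
is top-1.

## GO over-representation and term clustering

Per subtype, DE genes are tested against each gene set by the one-sided
hypergeometric over-representation test, BH-adjusted within (subtype,
namespace) and retained at adjusted p ≤ 0.05; the *enriched genes* of a term
are DE ∩ term. Terms whose enriched genes are more than 20% autopsy-associated
are removed (strictly greater; exactly 20% is kept).

Redundant terms are collapsed in two stages. Within a subtype, terms are
clustered on the Jaccard distance of their enriched gene sets (complete
linkage — the linkage is unstated in the source methodology, so the
environment default is used and config-exposed — cut at 0.66). Across
subtypes, the distance between two terms is the fraction of subtypes, among
those where both are enriched, that assign them to different within-subtype
clusters; pairs never co-enriched get distance 1 (a choice — the procedure
is silent on such pairs). Average-linkage clustering cut at 0.66 gives the
collapsed clusters, each named after the member term with the lowest mean
log p across subtypes.

For visualization, a matrix of the largest −log10 adjusted p per (collapsed
cluster, subtype) — trimmed at 10 — is L1-row-normalized (L1 chosen to match
the stated L1 distance; max-normalization would be the alternative reading),
Ward-clustered, cut at 2.5, and row groups of at least 5 retained.
(Subtype, cluster) pairs are embedded in 2D by UMAP (k = 10 neighbors,
spread 1.5, min_dist 0.2, fixed seed) on Jaccard distances of their enriched
gene unions.

Subtypes are compared as weighted pathway sets: the weight of pathway *i* in
subtype *k* is the inverse of the summed Jaccard similarities of its gene
set to all of *k*'s enriched pathways, **including itself** — this guarantees
w ≤ 1 and well-defined weights, and down-weights pathways detected from the
same genes. Subtype similarity is the weighted Jaccard (Σ min / Σ max, absent
pathways weighing 0). The similarity heatmap is clustered with average
linkage and cut at h = 1.2; note that with average (or complete) linkage on
a distance bounded by 1 all merge heights are ≤ 1, so the default cut yields
a single cluster — the cut only becomes active with a linkage whose heights
can exceed 1 (e.g. Ward, config-exposed) or a smaller h.

## Composition testing

Per subtype, the statistic is the absolute difference between the condition
means of within-sample proportions. The null permutes condition labels over
samples — the sample is the exchangeable unit — and the p-value uses the
add-one estimator (never 0). An exhaustive mode enumerates all label splits
for small cohorts and is tested against an independent enumeration. The
statistic itself is a design choice (the source names only "a permutation
test"); a studentized variant would also be exchangeable but the simple
difference is transparent and calibrates well (null p-values are uniform in
the test suite's 200-cohort check). Categories: p < 0.2 affected, p < 0.05
highly affected, smallest p per class top-1.

## The integrative impact score

Six ordinal metrics per subtype — expression similarity, composition, GO-term
count residual, GWAS enrichment, curated epilepsy-gene enrichment, DE-gene
count residual — each in {0, 1, 2, 3} with exactly one 3 per metric per
class, are combined as a weighted sum with a-priori weights 1.0, 0.66, 0.66,
0.66, 0.33, 0.66 respectively (maximum total 11.91). Top-1 is assigned after
the affected/highly-affected rules and overrides them for that subtype.
Whether top-1 for the count-residual metrics is global or per-class is not
specified in the source; per-class is used uniformly for all six metrics.

## Consensus co-expression modules

Co-expression analysis runs within a cell cluster (default: the level-2
annotation), deliberately, so that cell-type identity does not masquerade as
co-expression. Genes expressed in fewer than 20 cells of the cluster are
dropped; the rest are centered, scaled, decomposed into 120 PCs, ranked by
their largest absolute loading on any PC, and the top 5,000 kept.

The network is signed-hybrid: adjacency a = corᵝ for positive Pearson
correlations, 0 otherwise. β is the lowest power in 1..30 reaching a
scale-free fit R² ≥ 0.93, after discarding powers whose mean connectivity is
at or above the 95th percentile across powers; if none reaches the target,
the surviving power with the highest R² is used. Powers whose mean
connectivity falls below 0.05 are also discarded: a power that effectively
disconnects the network yields a degenerate degree histogram whose fit index
is meaningless. The fit index is the R² of the log-log regression of the
10-bin degree histogram.

Robustness comes from resampling: two-thirds of the cells are drawn without
replacement (default 100 times; the desk-scale tests use 20), a TOM is built
per resample (TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ, kⱼ) + 1 − aᵢⱼ), diagonal 1),
and the consensus is the element-wise 0.5-quantile. The consensus is applied
to the TOM (not the adjacency) — the source is ambiguous on this point.
Genes with zero variance in any resample are dropped.

Modules are average-linkage clusters of 1 − TOM. The dynamic hybrid cut is
implemented as: a static cut at 0.99 − 0.01·deepSplit of the dendrogram
height range (echoing the published default of 99% of the range), dissolving
clusters under 15 genes, followed by a PAM-like stage assigning each
unlabeled gene to the module with the highest mean TOM provided
1 − meanTOM falls below the cut height (the published algorithm's maximum
assignment distance). The published branch-shape criteria (core scatter,
gap statistics) are not reproduced; a plain static cut is available via
`cut_height`.

Refinement is driven by intramodular connectivity kIM(g, M) = Σ_{m∈M, m≠g}
TOM(g, m), computed on the consensus TOM for detection, merging and
reassignment alike (config can switch to adjacency): module pairs whose kIM
profiles over all genes correlate at ≥ 0.85 merge transitively; genes move
when their kIM to another module exceeds 1.25× the kIM to their own,
iterating with recomputation until stable (cap 50); genes whose kIM is not
significantly above the non-member kIM distribution of their module
(empirical one-sided rank p, BH at 0.05) are pruned. The pruning test is an
interpretation — the source names only "a t test" without a null.

The filter cascade is order-dependent and fixed: (i) a module whose genes
are ≥ 75% contained in a larger module with a weighted Pearson correlation
≥ 0.75 between the kIM profiles is removed (weights: the union-membership
indicator smoothed by kIM magnitude, w(g) = |kIM_M(g)| + |kIM_L(g)| on the
union, 0 elsewhere; plain Pearson available); (ii) modules whose
kIM · (−log10 p) dot product against injury/postmortem DE p-values is
extreme under kIM label permutation (10,000 replicates, p < 0.05) are
removed; (iii) module expression — the kIM-weighted (weights scaled to sum
1) sum of per-gene z-scored expression — is regressed on single-sample
indicators and on condition, and modules where any sample indicator's R²
exceeds the condition model's R² are removed ("any sample covariate" is read
as one indicator model per sample); (iv) the remaining modules keep only
those with a significant condition coefficient (two-sided OLS, α = 0.05),
reported with CI.

Curated-gene enrichment per surviving module uses a one-sided rank-sum test
of the curated genes' positions in the kIM ranking, with the variance
inflated by VIF = 1 + (m − 1)ρ̄, where ρ̄ is the mean pairwise expression
correlation of the in-module curated genes, floored at 0 — the correction
for correlated genes used by limma's `rankSumTestWithCorrelation`.
Bonferroni across tested modules.

## smFISH intensity normalization

Raw integrated densities (raw rather than background-subtracted, to avoid
infinities) of a target and a reference channel are log2-transformed; the
reference is quantile-normalized across sections (target distribution = the
mean of the sections' empirical quantile functions, the mean-of-sorted-
columns convention generalized to unequal section sizes by interpolation);
and the target is corrected by the reference's normalization shift,
target · (reference_normalized / reference), applied additively on the log2
scale (the scale of application is ambiguous in the source; log2 throughout
is used, with the raw-scale value reported as the back-transform). Group
comparisons are one-sided: Welch's t with Satterthwaite degrees of freedom,
or Mann–Whitney (exact for n ≤ 20 without ties, tie-corrected normal
approximation otherwise). Constant pooled values return p = 1 with a flag.

## The synthetic cohort generator

The generator emulates the cohort structure the pipeline targets: ~10
control and ~9 case samples, 20–40 subtypes in a fixed 4-level hierarchy
split into principal neurons and interneurons (names echo cortical
annotation schemes purely for readable reports), negative-binomial counts,
and planted ground truth for every downstream stage.

Counts are gamma-Poisson: each cell's expected expression is library size ×
subtype expression share × condition effect × module factor, with a shared
dispersion (default 0.15, the magnitude typical of UMI count overdispersion).
Subtype programs are log-normal multiplicative deviations (σ = 0.5) around a
common log-normal base expression; per-cell library sizes are log-normal
(σ = 0.25) around 2,500 counts, mean-normalized. Condition effects multiply
chosen genes of chosen subtypes by 2^(±lfc) in case cells. Planted modules
enter multiplicatively through a mean-one log-normal per-cell latent factor
scaling member-gene means — giving positive correlation structure detectable
by TOM without materially changing marginal means — optionally coupled to
condition by shifting the factor's log-mean in case cells. Composition
shifts scale a subtype's multinomial proportion in case samples. Per-subtype
cell counts per sample default to a mean of 40 (the source states only a
coverage floor, so this is exposed as a parameter). One global seed drives
independent per-sample substreams, so enlarging one sample leaves the others
bit-identical.

What the generator does **not** emulate: ambient RNA, doublets, batch
chemistry, gene-length or GC effects, realistic gene-gene correlation beyond
the planted modules and subtype programs, or the real dataset's gene panel.
Passing tests therefore demonstrate correctness of the statistical machinery
and recoverability of planted effects under idealized NB noise — not
performance on real tissue data.

Fixture generators produce GMT gene-set collections (uniform random terms
plus a designated subset over-sampling planted DE genes at a configurable
spike rate), curated/GWAS/autopsy gene-list files, and smFISH intensity
tables (log-normal noise around group means, cells split over sections).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale, as a
package choice: null calibration uses 15–200 cohorts of 5–6 subtypes with
10–20 cells per (sample, subtype) and 30–800 genes; DE null/recovery runs
use 10+9 samples × 800 genes; module recovery uses 300 genes × ~1,000 cells
× 20 resamples with three planted 30-gene modules at loading 0.9 (within-
module count correlation ≈ 0.5); the end-to-end impact recovery uses 6
subtypes × 11 samples × 400 genes over 10 seeds. Tolerances: oracle
comparisons at 1e-12 (1e-4 for the conditional-MLE scan, the scan's own
resolution); stochastic calibration checks at the thresholds stated in the
tests. Permutation p-values use the add-one estimator everywhere; BH is
computed NaN-safe; PCA uses the full SVD below 500 cells and a seeded
randomized solver above; all hierarchical clustering goes through
`scipy.cluster.hierarchy` with condensed distances.

## Known limitations

- The dynamic tree cut is a simplification of the published hybrid
  algorithm (no branch-shape criteria); planted-block structure is recovered
  exactly, but real dendrograms with nested structure may cut differently.
- The kIM pruning test and the weighted-Pearson overlap weights are
  documented interpretations of under-specified steps.
- Cell-level OLS for the module condition coefficient treats cells as
  independent, as in the source; a mixed model with sample random effects
  would be more conservative.
- The similarity score requires ≥ 3 control samples per subtype and a
  non-degenerate MAD; rare subtypes are flagged rather than scored.
- GO namespaces are taken from the GMT input (defaulting to BP); no ontology
  topology is used.
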