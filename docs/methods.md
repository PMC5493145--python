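# Methods

This note documents the models, defaults and numerical choices behind
`cocapipe`, and what the synthetic-data results do and do not demonstrate
about real cohorts.

## The stromal-contamination model and its filter

Bulk tumor RNA from liver-resident cancers mixes tumor-cell transcripts with
transcripts from admixed normal liver. A small set of hepatocyte genes is
expressed three to four orders of magnitude higher in normal liver than in
tumor cells, so even a few percent contamination dominates their measured
signal. Because the contamination fraction varies from sample to sample,
these genes acquire the largest variances in the cohort and crowd tumor
biology out of any top-variance gene selection; the resulting clusters track
the contamination gradient rather than tumor subtype.

The filter derives a tissue-specific list from a normal-tissue compendium of
per-tissue median log2 expression: a gene qualifies when its linear level in
the target tissue is at least `min_fold` (default 50, inclusive boundary)
times the maximum across all other tissues and its linear target level is at
least `min_level` (default 1, in the compendium's linear unit). Genes on the
list are removed outright — the measured values of a contaminated gene carry
no usable tumor signal at these fold ratios, so down-weighting or regression
would only launder noise. The default fold threshold is far below the
1,000–20,000× folds typical of the liver signature, so the filter's content
is insensitive to it over a wide range.

## Expression subtyping

* Variance filtering keeps the `ceil(fraction · n_genes)` genes of highest
  log2 variance (ties broken lexicographically). Variance, not MAD, because
  the confound of interest manifests exactly in variance.
* Hierarchical clustering defaults to 1 − Pearson distance with Ward
  linkage for feature matrices and Euclidean distance in PCA space; both
  are configurable. Cluster labels are renumbered in order of first
  appearance so output is invariant to internal label codes.
* Per-sample robustness is the silhouette width on the clustering distance,
  rescaled from [−1, 1] to [0, 1]. Degenerate cases (singletons, k = n)
  default to 1.
* PCA is computed by SVD of the gene-centered matrix; each component's sign
  is fixed so its largest-magnitude loading is positive.
* OPLS-DA is implemented as a NIPALS-style PLS on the centered, unit-variance
  matrix: per one-vs-rest contrast, `n_orthogonal` (default 1)
  label-orthogonal components are deflated before the predictive component
  is extracted; genes are ranked by the magnitude of their predictive
  loading, and a gene's reported weight is its largest-magnitude loading
  across contrasts. Selection is top-N or a |loading| threshold.
* Cluster transfer restricts the external matrix to shared discriminant
  genes (≥ 10 required), median-centers per gene as a minimal cross-dataset
  normalization, clusters, and matches labels to the reference clusters by
  centroid cosine similarity with a Hungarian one-to-one assignment —
  replacing visual matching with a reproducible rule.

## Signature scores and GSEA

The per-sample signature score is the mean over member genes of each gene's
cohort z-score (`mean_z`); a `median_raw` variant (per-sample median of
member expression) supports cross-cancer score comparisons where z-scoring
within a mixed cohort would remove the signal of interest. Zero-variance
genes are dropped with a warning.

GSEA uses the classic weighted running sum: walking down the ranked list,
hits add `|w|^exponent` (normalized to sum 1 over members; exponent default
1), misses subtract `1/(N − |S|)`; ES is the extremum of the running sum.
The null permutes gene labels — at cohort sizes of a few dozen samples a
phenotype-permutation null is too coarse — so NES is ES divided by the mean
|permuted ES| of the same sign and the p-value is the two-sided permutation
tail with the +1 correction (p ∈ [1/(n_perm+1), 1], hence slightly
conservative). Group associations of scores use two-sided rank-sum tests
after excluding samples with purity < 0.65 (expression-derived scores in
low-purity samples reflect stroma); BH correction is applied across groups,
and Spearman correlation is used for the cross-geneset anticorrelation
blocks, whose gene ordering is held identical across datasets so blocks are
directly comparable.

## Integrative clustering and COCA

Copy-number clustering operates only on recurrently altered loci: per locus
and direction the score is (fraction of samples beyond ±0.3 log-ratio) ×
(mean |log-ratio| among them); the null permutes locus labels within each
sample (preserving per-sample amplitude distributions), p-values pool null
scores across loci, and BH q ≤ 0.25 retains loci. This is a deliberate
simplification — a recurrence filter in the role a segmented-marker
algorithm plays for real arrays, not a reimplementation of one. Arm-level
events are handled by treating arms as loci.

Methylation clustering uses probes unmethylated in normals (mean beta
< 0.3) that gain ≥ 0.2 beta over the normal mean in ≥ 10% of tumors.

Consensus clustering resamples 80% of samples (default 100 runs), clusters
each subsample, and records per pair the co-clustering frequency among runs
containing both. The number of clusters is chosen by maximal mean
silhouette on the 1 − consensus distance over `k_range`; cuts that collapse
to a single cluster are excluded from selection. Robustness is again the
rescaled silhouette, now on consensus distance, so it measures stability
under resampling.

COCA builds the binary sample × (platform, cluster) membership indicator
and consensus-clusters its rows with a 1 − Jaccard distance; samples
missing from a platform are compared over mutually observed columns only.
Silhouette-based k selection on indicator data is biased toward coarse
partitions (a 2-cut of concordant fine structure is also crisp), so when a
target cluster count is known — as when an integrated four-cluster solution
is the analysis goal — `k_range` should be pinned to it; the demonstration
of four-subtype recovery does exactly that while leaving per-platform
cluster counts data-driven.

## Silencing statistics

A gene is called silenced in a sample when its promoter beta exceeds the
cohort-low reference (mean of the lowest-beta tertile — a stand-in for
adjacent-normal methylation, which real cohorts have only for a subset) by
≥ 0.3 and its expression z is ≤ −1. Calls co-occurring with a non-silent
mutation or a deep deletion (log-ratio ≤ −1) of the same gene are annotated
as conflicts and never reclassified: the mutual-exclusivity question is an
output, not an input, of the call.

The group screen runs three stages on high-purity samples (purity ≥ 0.65):
(1) promoter probes with in-group beta gain ≥ 0.2 at rank-sum BH q ≤ 0.05;
(2) their target genes with in-group expression decrease at BH q ≤ 0.05;
(3) genes whose promoter beta and expression are Spearman-anticorrelated at
rho ≤ −0.3 across the retained samples. Promoter mapping comes from the
probe annotation's promoter flag; no distance-based inference. All
thresholds are exposed; only the purity cutoff has an external anchor, the
others are conventional effect-size/FDR choices fixed before any tuning.

Fisher's exact test sums hypergeometric probabilities of all fixed-margin
tables no more probable than the observed one (tolerance factor 1 + 1e−7
against floating-point ties); odds ratios apply the Haldane 0.5 correction
when a cell is zero. Overlap tests are upper-tail hypergeometric.
Signature-correlated feature discovery flags a feature per dataset at
|Spearman rho| ≥ `rho_min` with the stated sign, reports features flagged in
≥ `min_datasets` datasets, and estimates the count expected by chance by
recomputing over sample-permuted scores; enrichment of observed over
expected uses the Fisher test.

Mutational-signature exposures are refit, not discovered: the cohort's
96-context frequency vector is regressed onto a fixed column-stochastic
signature matrix by non-negative least squares, exposures normalized to sum
1, and signatures with exposure ≥ 0.05 flagged enriched. De novo NMF
factorization is out of scope.

## The synthetic cohort generator

The generator's defaults describe a cohort of 38 samples, 2,000 genes, 600
probes, 200 loci and three planted subtypes, with 200 stromal genes at
1,000–20,000× linear fold, contamination ~ U(0, 0.3), purity ~ U(0.55,
0.95), log2 noise SD 0.5, Poisson mutation counts with mean 49 and a 66%
non-silent fraction. Specific analyses scale the cohort as noted below.

Semantics worth knowing:

* Expression mixes tumor and stromal signal linearly —
  `log2(tumor·(1−c) + normal·c + 1)` with Gaussian log2 noise — because
  contamination mixes linearly in reality; the stromal fold is a
  linear-scale statement. Planted subtype effects are applied on the
  observed log2 scale after mixing, so a planted effect size is realized as
  the stated group difference in the delivered matrix; recovery tests can
  therefore quote exact planted effect sizes.
* Methylation betas are drawn from Beta distributions around planted means
  with a concentration (dispersion) knob, and are treated as purity-adjusted
  tumor-cell fractions for the same reason. Planted silencing couples each
  gene's promoter probes to its expression through a per-sample dose latent
  with mean 1. Additional subtype-wide hypermethylation is planted outside
  promoters (CIMP-like), reflecting that the generator's promoter-hyper
  events are exactly its silencing events; unplanted probes carry a 30%
  baseline promoter annotation rate.
* Purity and contamination are sampled independently — DNA-based purity
  does not capture transcriptome stromal admixture, which is the
  motivating observation for keeping them distinct.
* Copy-number events scale with purity; mutation contexts are drawn from
  `signature_matrix @ exposures`; driver mutations are per-subtype
  Bernoulli events carried as hotspot records.
* The contamination-fraction distribution of real cohorts is not known;
  U(0, 0.3) is an illustrative default, exposed in the config.

What passing tests show: the pipeline's operations recover effects of the
planted form at the planted sizes, control their stated error rates on null
data, and agree with brute-force recomputation of their statistics. What
they do not show: robustness to batch effects, probe cross-reactivity,
copy-number segmentation artifacts, subtype structure that violates the
block-effect model, or any claim about a particular real cohort — real
cluster counts and gene lists are data-dependent.

## Problem sizes and determinism

Demonstration analyses use n = 60 (confound unmasking; 3 subtypes), n = 80
(COCA; 4 subtypes), n = 100 with 24 planted genes (silencing screen), 50
replicates at n = 40 for null calibration, and ~10,000 mutations for
exposure recovery — sizes at which the planted effects are identifiable
without being trivial. Every stochastic routine takes an explicit seed;
pipeline reruns with the same config and seed are byte-identical, and the
acceptance script derives all sub-seeds from its single `--seed`.

## Known limitations

* The recurrence filter is not a segmentation-aware peak caller; closely
  spaced co-altered loci are reported individually.
* Consensus k selection by silhouette can prefer coarse solutions on very
  clean block structure (see COCA note above); consensus-CDF-based
  selection is not implemented.
* OPLS-DA is fit per one-vs-rest contrast with a single predictive
  component; multi-component predictive subspaces are not supported.
* The exposure fit assumes the provided signature matrix spans the true
  processes; model selection over signature subsets is out of scope.
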