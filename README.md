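# cocapipe

Integrative multi-omics subtype discovery for small tumor cohorts, built
around the analysis problems that arise in bile-duct cancer (cholangio-
carcinoma) profiling: a handful of normal-liver genes expressed thousands of
fold above tumor levels contaminate bulk expression and dominate any
most-variable-gene clustering; per-platform cluster solutions (mRNA, DNA
methylation, copy number) disagree in detail; and promoter hypermethylation
can silence tumor suppressors in ways that are invisible to any single
platform.

The package provides, as a library plus a thin CLI:

* **Stromal-signature filtering** — derive a tissue-specific gene list from
  a normal-tissue expression compendium (gene kept when its linear level in
  the target tissue is ≥ `min_fold` × the maximum over other tissues) and
  remove those genes before clustering.
* **Expression subtyping** — top-variance selection, hierarchical / PCA
  clustering with silhouette-based robustness scores, OPLS-DA discriminant
  gene ranking, and transfer of a cluster solution onto an external cohort
  via shared discriminant genes with Hungarian centroid matching.
* **Signature scoring** — per-sample geneset scores (mean z or median raw),
  weighted running-sum GSEA with a gene-permutation null
  (ES, NES, permutation p), two-group rankings (signal-to-noise
  `(μ₁−μ₂)/(σ₁+σ₂)`), purity-filtered rank-sum group associations with BH
  q-values, and cross-geneset Spearman anticorrelation blocks.
* **Integrative clustering** — GISTIC-like recurrent-SCNA selection
  (frequency × mean |log-ratio| against a within-sample permutation null),
  cancer-specific CpG selection, consensus clustering over resampled runs,
  and cluster-of-clusters analysis (COCA): samples are re-clustered on the
  binary matrix of their per-platform cluster memberships with a
  1 − Jaccard distance.
* **Epigenetic-silencing statistics** — per-sample silencing calls (promoter
  beta gain × expression z, with mutual-exclusivity annotation against
  mutation and deep deletion), a three-stage group screen (hypermethylation
  × downregulation × methylation–expression anticorrelation), Fisher exact
  and hypergeometric overlap tests, signature-correlated feature discovery
  with a permutation chance expectation, and mutational-signature exposure
  fitting by non-negative least squares over trinucleotide spectra.
* **Synthetic cohort generator** — multi-platform cohorts with planted
  subtypes, stromal contamination, purity, driver mutations, and signature
  mixtures, with a complete ground-truth ledger, so every stage is testable
  without access-controlled data.

## Worked example

Generate a 60-sample cohort in which 200 stromal genes (10,000-fold higher
in normal liver) plus 0–30% contamination mask three planted subtypes, then
unmask them by filtering:

```python
from sklearn.metrics import adjusted_rand_score
from cocapipe import (CohortConfig, generate_cohort, derive_tissue_specific_genes,
                      filter_genes, hierarchical_cluster, select_top_variable)
from cocapipe.synthetic import liver_compendium

cohort = generate_cohort(CohortConfig(
    n_samples=60, n_genes=2000, n_stromal_genes=200,
    stromal_fold_range=(10_000, 10_000),
    contamination=("uniform", 0.0, 0.3), seed=0))
truth = cohort.samples["subtype"]

pre = hierarchical_cluster(select_top_variable(cohort.expression, 0.02), k=3)
print("pre-filter ARI :", round(adjusted_rand_score(truth, pre.labels), 3))

liver = derive_tissue_specific_genes(liver_compendium(cohort), "liver")
post = hierarchical_cluster(
    select_top_variable(filter_genes(cohort.expression, liver), 0.02), k=3)
print("liver genes    :", len(liver))
print("post-filter ARI:", round(adjusted_rand_score(truth, post.labels), 3))
```

Output:

```
pre-filter ARI : -0.02
liver genes    : 200
post-filter ARI: 1.0
```

Before filtering, the top-2% most-variable genes are essentially all
stromal, so the clustering tracks the contamination gradient (adjusted Rand
index ≈ 0 against the planted subtypes). The compendium-derived liver list
recovers all 200 planted stromal genes; removing them lets the same
clustering recover the subtypes exactly (ARI = 1).

The same cohort objects feed the rest of the pipeline — for example a full
run from YAML:

```sh
cocapipe run-all --config config.yaml --outdir run/ --seed 3
```

writes per-stage TSVs (`mrna_clusters.tsv`, `recurrent_scna.tsv`,
`coca_clusters.tsv`, `silenced_genes.tsv`, `signature_exposures.tsv`,
`cohort_summary.tsv`, ...) and a `manifest.json` with config hash, seed and
version; reruns with the same seed are byte-identical.

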