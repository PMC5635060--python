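# cnvmet

Integrative genomic/epigenomic subtyping for liver cancer cohorts profiled on
three matched platforms: DNA copy number (CNV, segmented log-ratios), DNA
methylation (MET, β-values) and mRNA expression (EXP, log2).

Hepatocellular carcinoma accumulates both copy-number aberrations and DNA
methylation changes, and each can deregulate transcription in *cis*. This
package implements the analysis strategy that identifies the genes whose
expression actually responds to those aberrations, uses them to define
molecular subtypes, and characterizes the subtypes clinically. It is aimed
at computational biologists who have gene-level matrices of the three
platforms for a tumor/non-tumor cohort (or want to study the method itself on
the bundled synthetic cohort generator).

## The method

1. **Correlation screen.** For each gene, the Pearson correlation *r* of its
   expression with its copy number (and, separately, its methylation) is
   computed across tumors, variance-stabilized with Fisher's transform
   *z* = ½ ln((1+*r*)/(1−*r*)), and standardized as *z*·√(n−3) ~ N(0,1) under
   independence. Genes with *z*·√(n−3) ≥ 1.96 for CNV-vs-EXP are **CNVcor**
   genes (dosage-driven); genes ≤ −1.96 for MET-vs-EXP are **METcor**
   (methylation-repressed). The skewness of the *r* distributions (D'Agostino
   test) summarizes the genome-wide asymmetry of both regulation modes.
2. **Aberration burden.** Per tumor: counts of CNVcor/METcor genes whose
   expression differs more than twofold from the non-tumoral mean
   (CNVcor_UP/DOWN, METcor_UP/DOWN), and of all genes beyond a ±0.2 fold
   difference in CNV (gain/loss) or β (hyper/hypo). Pairwise correlations of
   these frequencies measure the coupling between genomic and epigenomic
   deregulation.
3. **Subtypes.** Per platform, consensus non-negative matrix factorization
   (multiplicative Kullback–Leibler updates, random restarts) with the
   cluster number *k* ∈ 2…5 chosen by cophenetic correlation of the consensus
   matrix subject to a minimum cluster size of 10; across platforms, a joint
   Gaussian latent-variable model X_d = W_d Z + ε_d (shared (k−1)-dimensional
   Z, lasso-penalized loadings, EM) with k-means on E[Z|X] — an
   iCluster-style integration.
4. **Characterization.** Kaplan–Meier curves and log-rank tests for overall
   survival and time to recurrence (truncated at 5 years), χ² tests on
   clinical contingency tables, fold-change/permutation-t differential
   expression, differential mutation rates (>10 mutations, >5% rate spread),
   and a per-sample signed Kolmogorov–Smirnov enrichment score
   S = ±(−log₁₀ p(D±)) for gene signatures (stemness sets, HCC classifiers).

A fully synthetic cohort generator (`cnvmet.synthetic`) plants all of this
structure — CNV/MET-driven genes, subtype-specific segmental aberrations,
coupled per-sample burdens, subtype-linked survival, vascular invasion and
mutations — with known ground truth, so every stage is testable end to end.

## Worked example

```python
from cnvmet import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    synthetic=CohortConfig(seed=3),   # defaults: 64 tumors, 30 normals, 2000 genes
    n_restarts=10,
    seed=3,
)
report = run_pipeline(config)

screen = report.stages["corr_screen"]
clust = report.stages["clustering"]
char = report.stages["characterize"]
print(f"CNVcor genes: {screen['n_cnvcor']}   METcor genes: {screen['n_metcor']}")
print(f"skewness r(CNV,EXP) = {screen['skewness_cnv']:+.3f}   "
      f"r(MET,EXP) = {screen['skewness_met']:+.3f}")
print(f"burden coupling r = {report.stages['aberration']['burden_r']:.2f}")
print(f"NMF chose k = {clust['nmf_cnv_chosen_k']} (CNV), "
      f"{clust['nmf_met_chosen_k']} (MET); integrative k = {clust['icluster_primary_k']}")
print(f"subtype sizes: {clust['subtype_sizes']}")
```

prints

```
CNVcor genes: 245   METcor genes: 173
skewness r(CNV,EXP) = +1.663   r(MET,EXP) = -1.746
burden coupling r = 0.69
NMF chose k = 3 (CNV), 3 (MET); integrative k = 3
subtype sizes: {1: 34, 2: 11, 3: 19}
```

Reading the output: the screen found 245 dosage-driven and 173
methylation-repressed genes in a 2000-gene panel (the planted fractions are
10% and 5%; the excess over the planted counts is the expected ~2.5% one-tail
false-positive rate at the 1.96 cutoff). The positive/negative skewness pair
is the genome-wide signature of copy-number activation vs methylation
repression. The per-sample CNV and MET burdens are correlated at r = 0.69
(the generator plants 0.70), both platforms independently support three
subtypes, and the integrative clustering recovers them with the planted
34/11/19 size gradient.

The same pipeline is scriptable from the shell:

```bash
cnvmet simulate --seed 5 --out cohort/
cnvmet run --config analysis.yaml
cnvmet validate --train-config a.yaml --second-config b.yaml
```

## Layout

- `cnvmet.matrix` — validated gene×sample containers and annotations
- `cnvmet.synthetic` — ground-truth cohort generator
- `cnvmet.preprocess` — quantile normalization, fold differences, missingness
  filtering, kNN imputation, probe selection/collapse, binary segmentation,
  empirical-Bayes batch adjustment
- `cnvmet.screen` — correlation screen, Fisher transform, skewness,
  genomic-context summaries
- `cnvmet.aberration` — burden counting and frequency coupling
- `cnvmet.clustering` — consensus NMF, integrative latent-variable model,
  partition agreement
- `cnvmet.characterize` — survival, χ², permutation t, DEGs, mutations,
  signed KS enrichment
- `cnvmet.pipeline` / `cnvmet.cli` — orchestration, validation mode, CLI

See `docs/methods.md` for the modeling choices and their rationale.
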