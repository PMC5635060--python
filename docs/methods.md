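# Methods notes

This note records the models implemented in `cnvmet`, the tunable
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Correlation screen

Gene-wise Pearson correlations are computed over pairwise-complete samples
(after the filter → impute pipeline there are normally none missing; the
pairwise-complete path matters only when imputation is skipped). The Fisher
transform z = arctanh(r) is clamped at |r| = 1 − 1e−12 with a warning.

Selection thresholds the **standardized** statistic z·√(n−3), which is
N(0, 1) under independence, at ±1.96 — so the cutoff carries its usual
two-sided P < 0.05 meaning with one tail used per class (CNVcor positive,
METcor negative; dosage activates, methylation represses). Thresholding the
raw z instead is available (`standardized=False`) but has no fixed type-I
interpretation: at n = 64 the implied |r| cutoff of the standardized rule is
tanh(1.96/√61) ≈ 0.246.

Skewness uses D'Agostino's (1970) normalizing transformation of
g1 = m₃/m₂^{3/2} (two-sided normal p; n ≥ 9 enforced). The implementation
wraps `scipy.stats.skewtest`; the test suite re-derives the transform from
the textbook formulas as an independent check.

## Aberration burden

"More than twofold" deregulation is strict: |log2 fold difference| > 1.
The raw-aberration cutoff 0.2 is applied on each platform's native
fold-difference scale (Δlog-ratio for CNV, Δβ for MET) — one number, two
scales, as the field convention has it. Frequencies are normalized by the
size of the gene universe being counted so panels of different sizes are
comparable. Counts are monotone non-increasing in the cutoff by
construction.

## Preprocessing

* **Quantile normalization**: reference = row-wise mean of sorted columns;
  ties receive the average of the tied reference values; missing entries are
  left missing and incomplete columns are mapped through interpolated
  reference quantiles.
* **Missingness**: rows with > 30% missing are dropped at platform
  preprocessing; a 50% threshold is intended for a later matched-triplet
  stage. Both are config keys; both are established filtering conventions for
  this assay pairing and are deliberately not merged.
* **kNN imputation** works in row (gene) space with k = 10: distance is the
  RMS difference over co-observed columns, a missing entry takes the mean of
  the k nearest rows that observe that column, with column-mean fallback.
  Matches a quadratic brute-force oracle exactly in tests.
* **Probe handling**: the methylation probe universe is configurable —
  `paper` (autosomal, CpG-island-related or promoter-associated) or `all`
  (autosomal only) — because restricting to island/promoter contexts while
  also analyzing open-sea/gene-body composition is a genuine tension in this
  analysis design; we surface it rather than resolve it. Promoters are
  [TSS−2500, TSS) on the annotated strand; coordinates 0-based half-open.
  Multi-probe genes collapse to one representative probe: the probe closest
  to the gene's mean correlation (`mean_corr`, used for CNV) or the most
  negative one (`min_corr`, used for MET).
* **Segmentation** is a simplified binary segmentation (recursive best
  two-sample-t split accepted at permutation P < α = 0.01), not a faithful
  circular binary segmentation: no circularity, no pruning. At α = 0.01 an
  occasional spurious split inside a true segment is expected (~1% per
  interval) — boundary *placement* is the tested guarantee.
* **Batch adjustment** is parametric empirical-Bayes location/scale
  adjustment: gene-wise standardization by the pooled *within-batch*
  variance, batch effects γ (normal prior) and δ² (inverse-gamma prior,
  moment-matched) estimated by the standard fixed-point iteration, then
  back-transformed. δ̂² uses ddof = 0, which makes two statistically
  identical batches an exact fixed point. Agreement with scanpy's
  implementation is corr > 0.999 in tests. Note that EB shrinkage
  deliberately removes the *common* batch effect and leaves per-gene
  batch-mean sampling noise (sd ≈ √(2/n_b)) in place — per-gene batch means
  are not exactly equalized, and no parametric ComBat does so.

## Clustering

**NMF** uses the classic multiplicative KL updates. The conventional "50 iterations" setting is read as 50 random restarts (the `nrun` idiom of the
reference NMF framework); each restart runs to a relative objective change
below 1e−6 or 2000 updates. All restarts feed the consensus matrix; the best
final objective provides W/H. Consensus labels come from an average-linkage
cut of 1 − consensus; cophenetic correlation and average silhouette width on
that distance drive model selection (max cophenetic among k whose clusters
all have ≥ 10 members; ties → higher silhouette → smaller k).

Negative fold-difference inputs must be made non-negative. Two transforms
are provided: the column-wise min-shift, and the positive/negative split
(each gene g becomes g⁺ = max(x, 0) and g⁻ = max(−x, 0)). The pipeline
default is the **pos/neg split**: a min-shift leaves a large constant
background that absorbs one NMF factor, so a k-block structure only has
k−1 factors to land in and the true k becomes unstable, while the background
makes k = 2 look spuriously perfect. The split carries no background and
keeps a rank-k block structure rank-k.

**Integrative clustering** is the Gaussian latent-variable model
X_d = W_d Z + ε_d with a shared (k−1)-dimensional Z ~ N(0, I), diagonal Ψ_d,
fitted by EM from a deterministic SVD initialization (multi-starting EM adds
cost without benefit here; the k-means step keeps its restarts). After each
M-step the loadings of data type d are soft-thresholded at λ_d · max|W_d|
(λ = 0.2 default; λ = 0 is exactly probabilistic PCA — verified against the
top principal direction; λ ≥ 1 zeroes all loadings and is flagged
degenerate). Labels: k-means on E[Z|X] with `n_starts` restarts, seeded.
The Gaussian model is used for all platforms (no generalized-GLM variant);
β-values enter as fold differences, standardized gene-wise.

## Characterization

Survival endpoints are truncated at 60 months (time > 60 → censored at 60)
before Kaplan–Meier estimation (lifelines) and the k-group log-rank test.
Clinical χ² uses no continuity correction. The permutation t-test uses the
pooled-variance Student statistic, label permutations, and the +1-corrected
p = (1 + #{|t*| ≥ |t|})/(B + 1). Differential-expression calls require the
fold criterion (and optionally permutation p < α) against **each** other
subtype (intersection; `mode="union"` relaxes it). Differential mutations
need strictly more than 10 mutations and a max–min group rate difference
strictly above 5%.

The signature enrichment score is the signed one-sided two-sample KS
statistic of signature vs non-signature expression within one sample:
D⁺ = sup(F_rest − F_sig), D⁻ = sup(F_sig − F_rest), one-sided asymptotic
p = exp(−2·n_eff·D²) with n_eff = n₁n₂/(n₁+n₂), S = −log₁₀p(D⁺) if that
exceeds −log₁₀p(D⁻), the negative mirror otherwise, 0 on an exact tie.
The two-sample form is used because the signed-score definition names no
reference distribution; expression values and their ranks give identical D for
continuous data.

## Synthetic cohort generator

The generator emulates a matched tumor/non-tumor HBV-HCC cohort (defaults:
64 tumors, 30 normals, 2000 genes, three subtypes of proportions
0.20/0.36/0.44) with planted, recoverable structure:

* **Copy number** is segmental: genes are laid out on 44 autosome arms
  (chromosome-8 arms over-weighted for the planted CNV-driven genes by the
  `chr8_enrichment` multiplier), partitioned into 5-gene segments with
  states near {−0.5, 0, +0.5} log-ratio plus N(0, 0.05) measurement noise,
  so the optional segmenter has structure to find.
* **Methylation** is a logistic transform of a Gaussian latent (β strictly
  inside (0, 1)); events shift the latent by ±2.
* **Subtype identity is carried by which features aberrate**: every segment
  and every gene has a subtype affinity; event probability is the sample's
  burden rate × 3.0 in the matching subtype and × 0.1 elsewhere. Keeping
  rate × boost below the 0.95 probability cap (burden means
  0.28/0.18/0.09, within-subtype sd 0.06) avoids saturation that would
  otherwise decouple counts from the latent burden.
* **Burden coupling**: a sample's CNV and MET rates share the subtype mean
  and a correlated within-subtype Gaussian; since the shared means already
  induce between-subtype correlation, the within-subtype correlation is
  solved analytically so the **total** across-cohort correlation equals
  `burden_coupling` (0.7 default); infeasible targets are clamped with a
  warning.
* **Expression**: baseline N(7, 1) per gene plus `cnv_effect`·CNV for the
  planted CNV-driven genes and `met_effect`·(β − baseline-β) for the
  methylation-driven genes, plus N(0, `noise_sd`). Defaults
  cnv_effect = 2.0 and met_effect = −3.0 make a planted event move
  expression by about one log2 unit — enough for the twofold deregulation
  counting to see planted rather than noise-tail events, and consistent with
  segmented array log-ratios understating true copy-number change.
* **Clinic and outcome**: exponential OS/TTR with subtype-specific rates
  (TTR default 0.045/0.015/0.015 per month — hazard ratio 3 for the
  aggressive subtype), uniform censoring to 120 months, vascular invasion
  subtype-linked (78%/52%/21%), other covariates drawn from published
  marginal frequencies; a mutation table with a BAP1-like gene enriched in
  the aggressive subtype (15% vs 3%/5%) and a CTNNB1-like gene enriched in
  the favorable ones, over a background of subtype-indifferent recurrent
  genes; 2% MCAR missingness per platform by default.

`strong_signal_config()` defines the validation scenario used when the
question is "can the machinery recover an unambiguous structure": balanced
subtypes, flat burden profile (0.25/0.20/0.15), 180 tumors, no missingness.
The flat profile matters: with a steep burden gradient the k = 2 merge of
the two low-burden subtypes is stable across NMF restarts and the consensus
criterion cannot prefer k = 3; with subtype identity carried by segment
affinity instead, the k = 2 merge is ambiguous and the true k = 3 consensus
is essentially perfect.

What the generator does **not** emulate: probe-level array structure (it is
gene-level throughout), copy-neutral LOH, clonal heterogeneity, methylation
M-value statistics, covariate-dependent censoring, and any coupling between
mutations and the molecular matrices. Passing tests therefore demonstrate
the correctness and power of the machinery under the planted model, not
performance on real arrays.

## Problem sizes

Validation runs use cohorts of 180–300 tumors and 1000–2000 genes, NMF with
10 restarts, and 100-replicate batches for survival/mutation detection
rates — sizes at which each planted property is comfortably identified while
a full test run stays in the minutes range. The clustering k-scan covers
k ∈ 2…5 with a minimum cluster size of 10.

## Known limitations

* The segmenter is not a faithful circular binary segmentation (no
  circularity, no pruning) and is labeled as such.
* The integrative model is Gaussian-only; count/binary platforms would need
  a generalized variant.
* The asymptotic one-sided KS p-value is conservative for very small
  signatures; a warning fires when the profile is < 10× the signature size.
* Consensus-NMF model selection by maximum cophenetic correlation is known
  to favor k = 2 on data whose dominant axis is a one-dimensional gradient;
  the pos/neg transform mitigates but cannot remove this on strongly
  gradient-dominated cohorts.
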