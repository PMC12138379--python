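# Methods

This note documents the statistical procedures implemented in `hccomics`,
the defaults they ship with, what the synthetic cohort generator does and
does not emulate, and the numerical choices made where the underlying
publication record leaves the design open.

## Promoter-methylation silencing calls

Silencing detection follows the classic promoter-hypermethylation
workflow on Illumina 450k-style β-values (β ∈ [0, 1], fraction
methylated). Candidate probes must be

1. non-SNP-associated and autosomal,
2. within ±1,500 bp of the nearest transcription start site (the
   manifest's `tss_distance` is signed; the test uses |distance|),
3. unmethylated in normal tissue (mean normal β ≤ 0.2), and
4. methylated (β ≥ 0.3) in at least 5% of tumor samples, the
   denominator being all tumors in the β matrix.

Per candidate probe, tumors split into methylated (β ≥ 0.3) and
unmethylated (β < 0.3) groups; the probe is *selected* when the
methylated group's mean log2(TPM+1) expression of the paired gene is at
least 1.64 unmethylated-group standard deviations below the unmethylated
mean. Boundary conventions, fixed for determinism and configurable:

* β = 0.3 counts as methylated (the grouping rule is stated with ≥);
* the 1.64-SD criterion is inclusive ("at least … lower"), so exact
  equality selects the probe;
* the unmethylated SD is the sample SD (ddof = 1); probes with fewer
  than two unmethylated samples, an empty methylated group, or a gene
  absent from the expression matrix are reported untestable, never
  fatal.

A tumor is silenced at a selected probe when it is methylated there and
the gene's expression lies below the probe's unmethylated mean; a gene
is silenced in a sample when strictly more than half of its selected
probes agree (2/4 does not call, 2/3 does). The silencing burden is the
per-sample count of silenced genes. Expression enters on the
log2(TPM+1) scale by default; the probe→gene map is the manifest's
single nearest-TSS gene.

## Feature preparation

* `counts_to_tpm`: counts / gene length (kb), column-normalized to 1e6.
* Expression: genes with > 75% missing values are dropped on the TPM
  scale, then log2(TPM+1), then genes with population SD < 1.0 across
  tumors are dropped. With `log2_transform=False` the same filters apply
  to an already-log2 matrix, making the operation idempotent.
* Methylation: probes with > 20% missing values, SNP probes and
  sex-chromosome probes are removed; remaining missing entries are
  imputed by probe-space KNN (k = 5); the top 1,000 probes by median
  absolute deviation are kept. Array-level normalization (e.g. BMIQ) is
  deliberately out of scope — inputs are assumed normalized.
* KNN imputation (shared by methylation and drug-AUC): the distance
  between two rows is the root-mean-square difference over columns
  observed in both (RMS rather than raw Euclidean so overlap size does
  not dominate); a missing cell is the unweighted mean of the k nearest
  donor rows observed at that column, ties broken by row order. Observed
  values are never altered, and a cell with no co-observed donor raises
  an error naming the row.
* GISTIC lesions: discrete calls binarize as altered ⇔ call ≥ 1;
  negative values signal the continuous-CN dialect and raise.

## Subtype enrichment and burden

Every binary alteration (mutation, CNV amp/del, silencing) is tested per
subtype against all remaining samples with a two-sided Fisher exact test
on the 2×2 table; odds ratios use the Haldane–Anscombe +0.5 correction
when any cell is zero. BH correction runs across features *within* each
subtype — a narrower, more conservative family than pooling subtypes. A
feature is subtype-specific when q < 0.05 and the in-subtype altered
proportion exceeds the out-proportion. Subtypes with fewer than two
samples are excluded.

CNV burden sums the gene counts of altered lesions per sample,
separately for focal and arm levels, *without* deduplicating genes
shared by overlapping lesions (the configurable-by-construction choice;
metadata carries per-lesion gene counts, not gene lists). Mutation and
silencing burdens are column sums. Group comparisons use Kruskal–Wallis
plus pairwise two-sided rank-sum tests; stars follow the conventional
scheme (ns, *: P ≤ 0.05, **: ≤ 0.01, ***: ≤ 0.001, ****: ≤ 0.0001) on
the raw pairwise p, with BH q reported alongside.

## ssGSEA

For each sample, genes receive average ranks (largest expression =
largest rank). Walking the list in decreasing expression order, the
enrichment score is Σ over positions of (weighted in-set ECDF −
unweighted out-of-set ECDF), with in-set weights rank^α, α = 0.25. The
statistic is purely rank-based, so any strictly increasing per-sample
transform leaves scores unchanged — which also makes the raw-vs-log
input question moot. When a set covers every gene the out-of-set ECDF
is defined as zero (degenerate integral). Optional normalization divides
all scores by the global max − min of the matrix.

## Prognostic risk model

1. Univariate Cox screen per gene; keep Wald p < 0.01. Constant and
   non-convergent genes are dropped with a warning. Screening uses all
   samples before splitting (the procedure as described runs the screen
   ahead of the split); this is configurable by screening any subset.
2. Seeded 70/30 train/test split; L1-penalized Cox (coxnet path, 50
   alphas) on the standardized training matrix; the penalty maximizes
   the 10-fold cross-validated held-out Breslow log partial likelihood
   (the "cv-min" deviance rule, the less sparse of the common rules).
   Coefficients are mapped back to the raw log2 expression scale so that
   risk score = Σᵢ Coefᵢ × Exprᵢ holds literally.
3. Stratification: high risk ⇔ score strictly greater than the cutoff;
   the cutoff defaults to the median of the supplied scores, and test
   sets reuse the training median.
4. Log-rank test across groups (lifelines); IPCW cumulative/dynamic AUC
   at 1/3/5-year horizons (scikit-survival). The censoring distribution
   is estimated within the evaluated cohort by default: estimating it
   from the training partition is unusable whenever test follow-up
   extends past the training censoring support (the weight denominator
   hits zero). Horizons with no prior event or no at-risk control are
   reported as NaN, not errors.
5. Multivariate Cox of score + clinical covariates flags the score
   independent when its p < 0.05; near-perfect covariate collinearity
   (|r| > 0.999) is rejected before fitting.

Unpenalized fits use lifelines' default Efron tie handling; the
penalized path is Breslow (the coxnet implementation).

## Compound screen

Compounds with > 20% missing AUC (strict) are excluded; the rest are
KNN-imputed over compound profiles (k = 5). Per compound, a ridge
regression of AUC on per-panel-standardized shared-gene expression
(penalty by internal LOO cross-validation over a log-spaced grid)
predicts patient AUC. Candidates must satisfy all of:

* lower median predicted AUC in the top risk decile than the bottom
  decile,
* two-sided rank-sum p < 0.05 between those groups (the differential
  test and its cutoff are unstated upstream; 0.05 is the package
  default, configurable), and
* Spearman r(predicted AUC, risk score) < −0.35, strict, over **all**
  patients (not only the extreme groups).

No cross-panel batch harmonization beyond gene-wise per-panel
standardization is attempted; that standardization *is* the
harmonization contract here.

## Synthetic cohort generator

The generator plants known signal so every stage can be validated
end to end; its defaults are the study conditions used throughout the
tests and the acceptance script.

* β-values: beta-distribution mixture — unmethylated mode Beta(2, 18)
  (mean 0.10), methylated mode Beta(6, 4) (mean 0.60) — so thresholds
  stated on β apply directly. Decoy probes (SNP-flagged, chrX, distal,
  constitutively methylated in normals) exercise every candidate filter.
* Silencing: per subtype, `planted_silenced_genes` (8) genes are
  hypermethylated at all their promoter probes in `silencing_fraction`
  (0.4) of that subtype's tumors, and those (gene, sample) pairs lose
  `silencing_effect` (3.0) gene-SDs of log2 expression. A 1% sporadic
  methylation noise rate leaves null probes below the 5% candidacy rule.
* Expression: log2-normal, gene means U(3, 8), gene SDs U(1.1, 1.6)
  (so most genes clear the SD ≥ 1 filter); stored as TPM = 2^x − 1.
* Mutations/lesions: planted subtype-specific features at 60%/5%
  (mutations) and 50%/5% (lesions) in/out frequencies plus background
  features at 10%, matching the detectable-contrast regime the
  enrichment figures depict.
* Survival: exponential baseline hazard (the simplest generator that is
  exactly proportional-hazards), h0 = ln 2 / 730 days, linear predictor
  = Σ coef × standardized log2 expression of the planted prognostic
  genes (alternating-sign coefficients of magnitude `prognostic_effect`,
  default 1.0 per SD); independent exponential censoring tuned to a 30%
  nominal censoring rate; age and stage are independent nuisance
  covariates.
* Cell-line panel: sensitive compounds have AUC = center −
  scale·(r·program + √(1−r²)·noise) with r = 0.6 against a planted
  expression program (optionally weighted by signed coefficients to
  mirror a hazard signature); lower AUC = more sensitive. AUC entries go
  missing completely at random (5%).
* Cell counts: multinomial over subpopulation × tissue with positive
  preference multipliers on a uniform baseline.

Everything is deterministic given the config seed (one
`numpy.random.Generator` drives each bundle).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: realistic genome
coordinates; probe cross-reactivity; copy-number dosage effects on
expression or β; batch effects and array normalization artifacts;
correlated gene modules (genes are independent given the planted
structure); non-proportional hazards; informative censoring; cell-line
lineage structure. Recovery rates measured here are upper bounds for
cohorts with those complications.

## Problem sizes and test design

The validation suite runs the silencing oracle equivalence on 20 seeded
instances of ≤ 100 probes × 50 tumors, silencing recovery on 10 cohorts
of 200 tumors × 300 genes, null calibration on 20 zero-effect cohorts,
exact-test agreement exhaustively for all 2×2 tables with n ≤ 24 plus
400 random tables up to n = 200 (at 1e-10), ssGSEA oracle agreement on
50-gene toys (1e-8), risk recovery on one 400-tumor / 105-gene cohort
plus 50 random-score AUC replicates, and the drug screen on 20 seeded
cohort/panel pairs. These sizes were chosen to make each planted effect
comfortably detectable while keeping the whole suite fast enough to run
routinely.

## Known limitations

* The probe→gene map supports a single gene per probe; multi-gene
  promoter probes are out of scope.
* CNV burden requires per-lesion gene counts; true gene-level
  deduplication across overlapping lesions would need lesion gene lists.
* `univariate_cox_screen` fits one lifelines model per gene; it is meant
  for post-filter gene lists (10²–10⁴), not raw transcriptomes.
* The coxnet CV selects among the alpha path fit on the full training
  set; fold-specific paths may include alphas missing from some folds,
  which are then compared over the folds where they were fit.
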