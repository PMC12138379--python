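# hccomics

Analysis toolkit for multi-omics molecular-subtype characterization of
hepatocellular carcinoma (HCC) cohorts — and, more generally, any
tumor/normal cohort with methylation β-values, expression, copy-number
lesions, mutations and survival. It is aimed at computational biologists
who have subtype labels in hand (from whatever consensus clustering they
trust) and want the downstream characterization stack as tested,
reusable code:

* **Promoter-methylation silencing calls** — candidate CpG probes
  (non-SNP, autosomal, |TSS distance| ≤ 1,500 bp, mean normal β ≤ 0.2,
  methylated in ≥ 5% of tumors) are selected when the methylated group's
  (β ≥ 0.3) mean expression is at least 1.64 unmethylated-group SDs
  below the unmethylated mean; a gene is silenced in a sample when more
  than half of its selected probes agree, and the per-patient
  **silencing burden** counts silenced genes.
* **Subtype-specific alteration enrichment** — two-sided Fisher exact
  tests of each binary alteration (mutation, CNV amp/del, silencing)
  against subtype membership, Haldane–Anscombe-corrected odds ratios,
  BH-FDR within subtype; plus focal/arm CNV, mutation and silencing
  burden metrics with Kruskal–Wallis / rank-sum group comparisons.
* **ssGSEA** — the rank-weighted running-sum single-sample enrichment
  score, ES = Σ (weighted in-set ECDF − out-of-set ECDF) with weights
  rank^0.25.
* **Prognostic risk score** — univariate Cox screen (P < 0.01), seeded
  70/30 split, LASSO-Cox with 10-fold cross-validated penalty, risk
  score = Σᵢ Coefᵢ × Exprᵢ, median stratification, log-rank test, and
  IPCW time-dependent AUC at 1/3/5 years.
* **Compound prioritization** — AUC missingness filter (> 20% excluded)
  with KNN imputation, per-compound ridge regression from cell-line
  expression to drug AUC applied to patient expression, then candidates
  with lower predicted AUC in the top risk decile (rank-sum p < 0.05)
  and Spearman r < −0.35 against the risk score (lower AUC = more
  sensitive).
* **Synthetic multi-omics cohorts** — a planted-truth generator
  (bimodal β mixtures coupled to expression suppression, subtype-specific
  binary alterations, exponential proportional-hazards survival,
  cell-line drug panels with planted sensitivity programs) so the whole
  pipeline is testable without any external download.

`docs/methods.md` documents every procedure, default and numerical
convention in detail.

## Worked example

```python
import numpy as np
from hccomics import (CohortConfig, generate_cohort, run_silencing,
                      subtype_feature_enrichment)

cfg = CohortConfig(n_tumor=200, silencing_effect=3.0,
                   silencing_fraction=0.4, seed=1)
bundle = generate_cohort(cfg)

expr = np.log2(bundle.tumor_expression + 1.0)
res = run_silencing(bundle.manifest, bundle.normal_betas,
                    bundle.tumor_betas, expr)
print(f"candidate probes: {len(res.candidate_probes)}")
print(f"selected probes:  {int(res.probe_results['selected'].sum())}")
print(f"silenced genes:   {len(res.gene_calls)}")
print(f"mean burden:      {res.burden.mean():.2f} genes/sample")

calls = {(g, s) for g in res.gene_calls.index
         for s in res.gene_calls.columns[res.gene_calls.loc[g]]}
truth = bundle.truth.silenced_pairs
tp = len(calls & truth)
print(f"sensitivity:      {tp / len(truth):.3f}")
print(f"FDP:              {(len(calls) - tp) / len(calls):.3f}")

enr = subtype_feature_enrichment(res.gene_calls.astype(int),
                                 bundle.truth.subtype_labels)
spec = enr[enr["specific"]]
hit = sum(bundle.truth.silenced_genes.get(f) == s
          for f, s in zip(spec["feature"], spec["subtype"]))
print(f"subtype-specific silenced genes: {len(spec)} flagged, "
      f"{hit} match the planted subtype")
```

prints

```
candidate probes: 77
selected probes:  72
silenced genes:   24
mean burden:      3.19 genes/sample
sensitivity:      0.992
FDP:              0.003
subtype-specific silenced genes: 24 flagged, 24 match the planted subtype
```

The cohort plants 8 silenced genes per subtype (24 total), suppressed by
3 gene-SDs in 40% of each subtype's tumors. The caller recovers 99.2%
of the planted (gene, sample) pairs with a 0.3% false-discovery
proportion, and the enrichment stage assigns all 24 recovered genes to
their true subtype.

## Command line

Each pipeline stage is a subcommand over TSV/GMT files (`NA` =
missing; matrices are features × samples):

```
hccomics simulate   --out-dir cohort --seed 1 --with-ccl-panel
hccomics silencing  --tumor-betas cohort/tumor_betas.tsv \
                    --normal-betas cohort/normal_betas.tsv \
                    --expression cohort/tumor_expression.tsv \
                    --manifest cohort/manifest.tsv --out-dir out
hccomics enrich     --alterations cohort/mutations.tsv \
                    --labels cohort/labels.tsv --out-dir out
hccomics ssgsea     --expression cohort/tumor_expression.tsv \
                    --gmt cohort/gene_sets.gmt --out-dir out
hccomics risk       --expression cohort/tumor_expression.tsv \
                    --survival cohort/survival.tsv --seed 1 --out-dir out
hccomics drugscreen --ccl-expression cohort/ccl_expression.tsv \
                    --auc cohort/ccl_auc.tsv \
                    --patient-expression cohort/tumor_expression.tsv \
                    --risk-scores out/risk_scores.tsv --out-dir out
```

All stages are byte-deterministic given the same inputs, config and
seed. `--config file.yaml` supplies option overrides; explicit flags
win.

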