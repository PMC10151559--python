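# mmpscore

Gene-set-driven molecular subtyping and prognostic scoring for tumor
expression cohorts.

Many cancer transcriptomics studies follow the same analysis arc: take a
curated gene panel (here, a matrix-metalloproteinase — MMP — pathway panel),
discover molecular subtypes by resampling **consensus clustering**, derive
subtype differential expression, compress it into a per-patient **risk
score**, dichotomize at the median, and characterize the high/low groups with
survival, clinicopathological, mutation and drug-response statistics.
`mmpscore` implements that full arc as a tested, reusable library and CLI,
together with a synthetic-cohort generator that plants the structure the
analysis assumes (K expression subtypes, a latent prognostic factor, a
proportional-hazards survival model, group-dependent mutation burden) so
every stage can be validated by ground-truth recovery.

## The method

1. **Consensus clustering.** For each candidate K, samples are repeatedly
   subsampled (default 100 resamples at 80%) and clustered (agglomerative,
   average linkage, distance = 1 − Pearson correlation over the gene panel).
   The consensus matrix entry M_K[i, j] is the fraction of co-draws in which
   i and j co-cluster. K is selected from the area A(K) under the empirical
   CDF of consensus entries via the relative delta-area rule:
   Δ(K) = (A(K) − A(K−1)) / A(K−1), keeping the largest K with Δ(K) ≥ 0.1.
2. **Differential expression.** One-vs-rest moderated-t tests per cluster
   (empirical-Bayes variance shrinkage, Benjamini–Hochberg across all
   gene × contrast tests); a gene is a DEG when adjusted p < 0.05 and
   |log2FC| > 1 in any contrast.
3. **Signatures and score.** Clusters are ordered best → worst prognosis by
   Kaplan–Meier survival at the largest common follow-up; DEGs positively
   correlated (Spearman) with that ordinal form signature A (risk genes),
   negatively correlated ones signature B. Both are reduced by **Boruta**
   (shadow-feature random-forest selection). Each signature is summarized by
   the first principal component of its centered/scaled submatrix, oriented
   to correlate positively with the signature's mean expression, and

       score_i = PC1A_i − PC1B_i

   Patients are split into high/low groups at the median score. The PC1
   loadings, gene means and scales are frozen so external cohorts are
   *projected*, never refit.
4. **Downstream statistics.** Kaplan–Meier curves and k-sample log-rank
   tests per endpoint (OS/PFS/DSS/DFS), univariate Cox regression
   (Newton–Raphson, Breslow ties), IPCW time-dependent AUC at 12/24/36/48/60
   months, Kruskal–Wallis / Wilcoxon comparisons against ordinal stage
   covariates, per-gene logistic mutation association with tumor mutation
   burden comparison, and ridge-regression drug-sensitivity (log-IC50)
   imputation from a reference expression panel.

## Worked example

```python
import numpy as np
from mmpscore import (CohortSpec, GeneSet, generate_cohort, run_consensus,
                      moderated_deg_table, filter_degs, assign_signatures,
                      fit_scores, logrank_test, time_dependent_auc)

cohort = generate_cohort(CohortSpec(n_samples=300, k_true=3, seed=0))
panel = GeneSet("panel", frozenset(cohort.truth["cluster_genes"]))

consensus = run_consensus(cohort.expression, panel, k_range=range(2, 7),
                          reps=50, seed=0)
print("selected K:", consensus.selected_k)

degs = filter_degs(moderated_deg_table(cohort.expression, consensus.labels))
print("DEGs:", len(degs))

pair = assign_signatures(cohort.expression, degs, consensus.labels,
                         cohort.clinical, endpoint="OS")
scores = fit_scores(cohort.expression, pair)
print("signature sizes:", len(pair.signature_A), "/", len(pair.signature_B))

os_data = cohort.clinical.endpoint("OS")
lr = logrank_test(os_data["time"], os_data["event"],
                  scores.groups.loc[os_data.index])
print(f"OS log-rank: chi2={lr.chi2:.1f}, p={lr.p:.2e}")

auc = time_dependent_auc(os_data["time"], os_data["event"],
                         scores.scores.loc[os_data.index])
print("AUC(36 mo):", round(auc.auc[36.0], 3))
```

Output:

```
selected K: 3
DEGs: 103
signature sizes: 50 / 53
OS log-rank: chi2=89.6, p=2.96e-21
AUC(36 mo): 0.816
```

The delta-area rule recovers the three planted subtypes; 103 of the 205
genes clear the DEG thresholds (the 45-gene panel plus 60 planted signature
genes carry real signal, 100 noise genes do not); the median split of the
PC1-difference score separates survival decisively (the low-score arm is the
long-lived one, matching the planted hazard direction); and the score
discriminates 36-month survivors at AUC ≈ 0.82.

The same run is available from a shell:

```bash
mmpscore simulate --n-samples 300 --k-true 3 --seed 0 --outdir cohort/
mmpscore run-all --config config.yaml      # see PipelineConfig for keys
```

## Layout

| module | contents |
| --- | --- |
| `mmpscore.data_io` | delimited expression/clinical tables, GMT gene sets, MAF reduction, sample alignment |
| `mmpscore.synthetic` | planted-cohort and drug-panel generators with ground truth |
| `mmpscore.consensus` | consensus clustering, CDF/delta-area K selection, PCA QC projection |
| `mmpscore.degs` | moderated-t one-vs-rest differential expression, BH adjustment |
| `mmpscore.boruta` | shadow-feature all-relevant selection |
| `mmpscore.scoring` | signature assignment, PC1-difference score, median split, frozen projection |
| `mmpscore.survival` | Kaplan–Meier, k-sample log-rank, Breslow Cox, IPCW time-dependent AUC |
| `mmpscore.associations` | rank tests, mutation association, ridge drug-response imputation |
| `mmpscore.pipeline` / `mmpscore.cli` | YAML-driven orchestration and the `mmpscore` command |

See `docs/methods.md` for the statistical details, defaults and limitations.
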