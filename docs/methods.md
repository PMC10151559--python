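# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions that matter for reproducibility.

## Consensus clustering and the choice of K

Samples are clustered over a curated gene panel by resampling consensus: for
each of `reps` resamples (default 100) a fraction `p_item` (default 0.8) of
samples is drawn without replacement, and an agglomerative base clusterer
(average linkage, distance 1 − Pearson correlation between sample profiles)
is cut at each candidate K (default 2–9). The consensus entry M_K[i, j] is
the number of resamples in which i and j co-cluster divided by the number in
which both were drawn; pairs never co-drawn score 0 and are logged. Resample
index sets are drawn once and reused across K, so per-K matrices differ only
through the clustering, not the sampling. Final labels come from
agglomerative clustering of 1 − M at the selected K, not from any single
base run.

K is selected from the area under the empirical CDF of off-diagonal
consensus entries. For an empirical CDF this area is exactly
1 − mean(entries). With Δ(K_min) = A(K_min) and
Δ(K) = (A(K) − A(K−1)) / A(K−1), the selected K is the largest candidate
with Δ(K) ≥ `delta_threshold` (default 0.1). This is a reproducible
surrogate for the conventional visual elbow reading of the CDF and
delta-area plots; the threshold is a config key, and the per-K A and Δ
values are always written so the decision can be audited. The area is
non-decreasing in K on the same data; the suite asserts this within 1e−9.

The PCA projection (samples as observations, genes centered and scaled to
unit variance, constant genes dropped with a warning) is a QC device only;
no decision depends on it.

## Differential expression

Each cluster is contrasted one-vs-rest, which gives every gene a *signed*
log2 fold change per cluster — required later to split genes into up/down
signatures. Gene-wise pooled variances are shrunk toward a scaled
inverse-chi-square prior fit by the standard moments method on log sample
variances (digamma/trigamma matching, with the trigamma inverse solved by
Newton). The moderated t uses the augmented degrees of freedom d0 + d;
`prior_df=0` switches shrinkage off and recovers the ordinary pooled t
exactly (asserted against an independent implementation to 1e−9).
Benjamini–Hochberg adjustment spans all gene × contrast tests jointly, and a
gene is a DEG when adjusted p < 0.05 and |log2FC| > 1 in at least one
contrast (union rule; thresholds configurable). Zero-variance genes carry no
signal and get t = 0, p = 1 by convention.

## Signatures, Boruta, and the PC1-difference score

Clusters are ordered best → worst prognosis by their Kaplan–Meier survival
evaluated at the largest follow-up time common to all clusters (the shortest
of the per-cluster maxima), so the ordinal *increases with worse prognosis*.
Each DEG's Spearman correlation with that ordinal assigns it to signature A
(r > 0: risk genes) or B (r < 0); exact zeros are excluded and logged. This
orientation is load-bearing: it makes signature A collect risk genes, so a
*high* score marks poor prognosis and the low-score arm of the median split
is the long-lived one whenever the signatures are prognostic.

Boruta reduces the combined signature gene set (one joint run) against the
consensus cluster labels: each iteration appends a row-shuffled shadow copy
of every undecided feature (padded to at least five shadow columns so the
max-shadow threshold remains a meaningful null reference late in the run),
fits a random forest, and scores a hit for every feature beating the best
shadow importance. Two one-sided binomial tests on the cumulative hit count
(success probability ½, Bonferroni-corrected across all input features)
confirm or reject; whatever survives `max_iter` iterations (default 50) is
tentative and excluded from scoring. A single iteration can never reach
significance, so everything stays tentative — the intended degenerate case.
If reduction empties a signature the pipeline falls back to the unreduced
signature pair with a warning rather than aborting.

Each signature is summarized by the first right-singular vector of its
centered, unit-variance-scaled sample × gene submatrix; per-sample PC1
scores are oriented so they correlate positively with the signature's mean
expression (PC1 sign is otherwise arbitrary). The per-patient score is
PC1A − PC1B, dichotomized at the median (score > median → high). The PC1
weights, training means and scales are frozen in the score model; external
cohorts are projected with those frozen statistics — genes missing from the
new cohort contribute zero after centering (training-mean imputation), with
a hard error below 70% gene overlap per signature (configurable). The
median split is recomputed within each projected cohort. Projecting the
training cohort onto itself reproduces the training scores to machine
precision, which the suite asserts at 1e−12.

## Survival analysis

Kaplan–Meier estimation uses the product-limit estimator (lifelines), with
censoring tied to an event time handled after the event. The k-sample
log-rank test is computed directly from per-group observed and expected
event counts with the hypergeometric covariance (pseudo-inverse quadratic
form over k − 1 groups), so O and E are part of the result; it agrees with
lifelines' implementation to 1e−8 and, on tie-free two-group data, with the
Cox score test to 1e−6. The univariate Cox fit maximizes the Breslow-ties
partial likelihood by Newton–Raphson (tolerance 1e−8 on the step, 50
iterations, steps clipped to ±5 to damp early overshoot). Breslow ties were
chosen as the simplest reproducible convention; note this is a deliberate
departure from lifelines' Efron default, which is why the fit is authored
here and cross-checked against a brute-force grid maximization of the same
likelihood. Constant covariates return beta = 0 with infinite standard
error, flagged; diverging fits (monotone likelihood / complete separation)
are flagged, never silently returned.

The time-dependent AUC is the cumulative-case / dynamic-control estimator
with inverse-probability-of-censoring weights from the Kaplan–Meier estimate
of the censoring distribution: cases at horizon τ are subjects with an
observed event by τ (weight 1/G(T⁻)), controls are subjects observed beyond
τ (weight 1/G(τ)); tied marker values receive half credit, so a constant
marker scores exactly 0.5 and, without censoring, the estimator reduces to
exhaustive pair counting. Default horizons are 12, 24, 36, 48 and 60
months. Horizons with no cases or no controls (or with G = 0) yield NaN
with a warning.

## Association statistics

Two-group comparisons use the Wilcoxon rank-sum test — exact enumeration
when both groups have ≤ 10 tie-free observations, otherwise the
tie-corrected normal approximation; k-group comparisons use Kruskal–Wallis.
Nonparametric tests were chosen throughout to match the box-plot style of
group comparison; significance stars map (\*, \*\*, \*\*\*, \*\*\*\*) to
(0.05, 0.01, 0.001, 0.0001).

Per-gene mutation association is an unadjusted logistic regression (IRLS)
of mutation status on the low-score-group indicator, so an odds ratio above
1 means more mutations among low-score patients; genes mutated in fewer
than 10 samples are skipped (degenerate fits), zero cells fall back to the
Haldane–Anscombe 0.5-corrected closed form (flagged), and Wald p-values are
BH-adjusted across tested genes. Tumor mutation burden (count of qualifying
variant rows per sample, after excluding Silent/Intron/UTR/Flank/IGR/RNA
classes by default) is compared between score groups by rank-sum.

Drug-response imputation fits ridge regression on a reference panel of
cell-line expression and log-IC50, over the genes shared with the cohort
(error below 50% overlap), standardized on reference statistics; the
penalty is fixed or chosen by 5-fold cross-validation over a 17-point log
grid spanning 1e−3–1e5. Externally computed covariates (MSI, immune
infiltration, immune-evasion scores) are consumed as generic per-sample
tables; this package does not compute them.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, with the
ground truth returned for recovery tests:

* **Cluster genes** (default 45, matching the curated panel size) get
  per-cluster Gaussian means with two equal-variance components: a shared
  severity gradient (random per-gene slope times the standardized subtype
  index) and subtype-specific random offsets, both scaled by
  `cluster_separation` (default 2.5 log2 units). The gradient emulates the
  graded panel expression across prognosis-ordered subtypes that the
  signature construction relies on; the random offsets keep the K groups
  mutually distinct so consensus clustering can resolve them. Either
  component alone breaks one half of the pipeline: purely random offsets
  give subtypes whose leading principal component is unrelated to prognosis,
  and a pure gradient collapses the delta-area rule to K = 2.
* The **latent prognostic factor** f is the standardized subtype index plus
  N(0, 0.5²) noise (the noise SD is fixed, not a spec parameter: large
  enough that f is not a relabeling of the subtype, small enough to be
  recoverable). **Signature genes** (default 60, half up / half down) load
  on f with ±`signature_effect` plus N(0, noise_sd²); noise genes carry no
  structure.
* **Survival** is exponential proportional hazards,
  h(f) = h₀·exp(`hazard_log_hr`·f), with h₀ = ln 2 / 36 so median survival
  at f = 0 is 36 months — placing the default 12–60-month AUC horizons
  inside the observed follow-up. Censoring thins a `censor_rate` fraction of
  subjects to a uniform time on (0, T), so the empirical censoring fraction
  is unbiased for the target by construction.
* **Mutations**: per-sample burden is Poisson with a per-subtype mean
  (default 8/6/4, highest in the best-prognosis group, matching the
  direction in which lower-score patients carry more mutations), spread
  over a 60-gene panel by a long-tailed (1/rank) multinomial.
* **Stage covariates** (T/N/M/G/TNM) are quantile bins of f plus
  N(0, 0.75²) noise.

One global seed expands through `SeedSequence.spawn` into per-component
child generators, so adding a component never perturbs earlier draws and
identical specs are bit-identical.

What the generator does **not** emulate: library-size or batch artifacts,
gene–gene correlation beyond the planted factors, non-proportional hazards,
informative censoring, real mutation hotspot structure, or real gene
identities. Recovery results therefore demonstrate the pipeline's internal
correctness and statistical calibration under its own assumptions — not
performance on any real cohort.

## Problem sizes and determinism

The test and reproduction runs use deliberately modest sizes — 150–300
samples for cohort-level recovery (with 2 000 reserved for the Cox
large-sample consistency check), 50 consensus resamples over K = 2–6, 500
null / 200 alternative simulations for log-rank calibration, and Boruta at
500 × 50 with 50 iterations — chosen as the smallest sizes at which the
planted effects are decisively recoverable. Every stochastic step takes an
explicit seed; the pipeline report is byte-identical across reruns of the
same configuration and contains no timestamps.

## Known limitations

* The delta-area threshold rule is a surrogate for a visual judgment; on
  weakly structured data it tends toward the smallest candidate K.
* The moderated-t model assumes roughly Gaussian log-expression within
  clusters; heavy-tailed counts should be transformed upstream (the package
  assumes log2-scale input and performs no normalization).
* Boruta against cluster labels selects features relevant to *subtype
  separation*; features prognostic but orthogonal to the subtypes can be
  discarded.
* The projection requires the frozen genes' scale to be comparable in the
  new cohort; cross-platform transfers (e.g. RNA-seq → microarray) may need
  upstream harmonization that is out of scope here.
* Univariate Cox only; no multivariable model building or
  proportional-hazards diagnostics.
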