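"""Score-vs-covariate association statistics.

Two-group comparisons use the Wilcoxon rank-sum test (exact enumeration for
small tie-free samples, otherwise the tie-corrected normal approximation);
k-group comparisons use Kruskal-Wallis.  Per-gene mutation association is an
unadjusted logistic regression of mutation status on the score-group
indicator (IRLS via statsmodels), falling back to the Haldane-Anscombe
0.5-corrected closed form when a 2x2 cell is empty.  Drug response is
imputed by ridge regression trained on a reference panel of cell-line
expression and log-IC50 values, with genes standardized on reference
statistics and the penalty optionally chosen by 5-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from statsmodels.stats.multitest import multipletests

from .data_io import DataError, ExpressionMatrix, MutationMatrix

logger = logging.getLogger("mmpscore")

#: Figure-legend significance stars.
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thresh, stars in STAR_THRESHOLDS:
        if p < thresh:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """A rank-test comparison of one covariate across groups."""

    covariate: str
    groups: list
    statistic: float
    p: float
    n: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)
    test: str = "wilcoxon"

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass
class GeneMutationAssoc:
    """Logistic association of one gene's mutation status with score group."""

    gene_id: str
    odds_ratio: float
    beta: float
    se: float
    p: float
    counts: dict = field(default_factory=dict)  # mutated/wild x low/high
    corrected: bool = False  # Haldane-Anscombe applied
    q: float = float("nan")


def rank_test(values, groups, mode: str = "auto", covariate: str = "") -> GroupComparison:
    """Nonparametric comparison of ``values`` across ``groups``.

    ``mode``: ``two-sample`` (Wilcoxon rank-sum; exact when both n <= 10 and
    tie-free), ``k-sample`` (Kruskal-Wallis with tie correction), or ``auto``
    (by group count).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = list(pd.unique(g))
    samples = [v[g == lv] for lv in levels]
    for lv, s in zip(levels, samples):
        if s.size == 0:
            raise DataError(f"group {lv!r} has no observations")
    if len(levels) < 2:
        raise DataError("rank test needs >=2 groups")
    if mode == "auto":
        mode = "two-sample" if len(levels) == 2 else "k-sample"
    if mode == "two-sample":
        if len(levels) != 2:
            raise DataError(f"two-sample mode with {len(levels)} groups")
        a, b = samples
        tie_free = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        method = "exact" if (a.size <= 10 and b.size <= 10 and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p, test = float(res.statistic), float(res.pvalue), f"wilcoxon-{method}"
    elif mode == "k-sample":
        if all(np.array_equal(np.sort(s), np.sort(samples[0])) for s in samples[1:]):
            stat, p = 0.0, 1.0  # identical multisets: H = 0 by construction
        else:
            res = stats.kruskal(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "kruskal-wallis"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(
        covariate=covariate, groups=levels, statistic=stat, p=min(p, 1.0),
        n={lv: int(s.size) for lv, s in zip(levels, samples)},
        medians={lv: float(np.median(s)) for lv, s in zip(levels, samples)},
        test=test,
    )


def mutation_burden_compare(burden: pd.Series, score_groups: pd.Series) -> GroupComparison:
    """Rank-sum comparison of per-sample variant burden between score groups."""
    b = burden.reindex(score_groups.index)
    if b.isna().any():
        raise DataError("burden missing for some scored samples")
    if (b < 0).any() or (b != b.astype(int)).any():
        raise DataError("burdens must be non-negative integers")
    return rank_test(b.to_numpy(dtype=float), score_groups.to_numpy(),
                     mode="two-sample", covariate="mutation_burden")


def _logistic_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Closed-form log-odds and SE of a 2x2 table (saturated logistic fit).

    Layout: a = mutated&exposed, b = wild&exposed, c = mutated&unexposed,
    d = wild&unexposed.
    """
    beta = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return beta, se


def per_gene_mutation_assoc(
    mutations: MutationMatrix,
    score_groups: pd.Series,
    min_mutated: int = 10,
) -> list[GeneMutationAssoc]:
    """Per-gene logistic regression of mutation status on score group.

    The predictor is the indicator of the *low*-score group, so an odds
    ratio above 1 means the gene is more often mutated in low-score
    patients.  Genes mutated in fewer than ``min_mutated`` samples are
    skipped; zero cells trigger the Haldane-Anscombe 0.5 correction
    (flagged).  Wald p-values are BH-adjusted across tested genes.
    """
    samples = [s for s in score_groups.index if s in mutations.values.columns]
    if len(samples) < len(score_groups):
        logger.info("per_gene_mutation_assoc: %d scored sample(s) absent from "
                    "mutation matrix", len(score_groups) - len(samples))
    grp = score_groups.loc[samples]
    if not set(grp.unique()) <= {"high", "low"}:
        raise DataError("score groups must be 'high'/'low'")
    x = (grp == "low").astype(int).to_numpy()
    results: list[GeneMutationAssoc] = []
    for gene in mutations.gene_ids:
        y = mutations.values.loc[gene, samples].to_numpy()
        if y.sum() < min_mutated:
            continue
        a = float(((y == 1) & (x == 1)).sum())  # mutated, low
        b = float(((y == 0) & (x == 1)).sum())  # wild, low
        c = float(((y == 1) & (x == 0)).sum())  # mutated, high
        d = float(((y == 0) & (x == 0)).sum())  # wild, high
        corrected = min(a, b, c, d) == 0
        if corrected:
            logger.info("per_gene_mutation_assoc: zero cell for %s; "
                        "Haldane-Anscombe correction applied", gene)
            beta, se = _logistic_2x2(a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        else:
            X = sm.add_constant(x.astype(float))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            beta, se = float(fit.params[1]), float(fit.bse[1])
        z = beta / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(GeneMutationAssoc(
            gene_id=gene, odds_ratio=float(np.exp(beta)), beta=beta, se=se, p=p,
            counts={"mutated_low": a, "wild_low": b, "mutated_high": c, "wild_high": d},
            corrected=corrected,
        ))
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def ridge_drug_response(
    reference_expr: ExpressionMatrix,
    reference_log_ic50: pd.Series,
    cohort_expr: ExpressionMatrix,
    lam: float | str = "cv",
    min_overlap: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Impute per-sample log-IC50 from expression via ridge regression.

    The model is trained on the reference panel (cell lines) over the genes
    shared with the cohort, standardized on *reference* statistics; ``lam``
    is the ridge penalty, or ``"cv"`` to select it by 5-fold cross-validation
    over a log grid.  Predictions are returned on the reference log-IC50
    scale.
    """
    shared = [g for g in reference_expr.gene_ids if g in cohort_expr.values.index]
    frac = len(shared) / reference_expr.n_genes
    if frac < min_overlap:
        raise DataError(
            f"gene overlap {frac:.0%} below threshold {min_overlap:.0%}"
        )
    Xr = reference_expr.values.loc[shared].to_numpy().T  # lines x genes
    y = reference_log_ic50.reindex(reference_expr.sample_ids).to_numpy(dtype=float)
    mu, sd = Xr.mean(axis=0), Xr.std(axis=0)
    keep = sd > 0
    Zr = (Xr[:, keep] - mu[keep]) / sd[keep]
    Xc = cohort_expr.values.loc[shared].to_numpy().T
    Zc = (Xc[:, keep] - mu[keep]) / sd[keep]
    if lam == "cv":
        grid = np.logspace(-3, 5, 17)
        model = RidgeCV(alphas=grid, cv=5)
    else:
        model = Ridge(alpha=float(lam))
    model.fit(Zr, y)
    pred = model.predict(Zc)
    return pd.Series(pred, index=cohort_expr.sample_ids, name="predicted_log_ic50")


def clinicopath_association(
    scores: pd.Series,
    clinical_covariates: pd.DataFrame,
) -> list[GroupComparison]:
    """k-sample rank test of the score across each ordinal covariate's levels.

    Covariates with a single non-empty level are skipped with a warning.
    """
    out: list[GroupComparison] = []
    common = scores.index.intersection(clinical_covariates.index)
    s = scores.loc[common]
    for cov in clinical_covariates.columns:
        levels = clinical_covariates.loc[common, cov].dropna()
        if levels.nunique() < 2:
            logger.warning("clinicopath_association: covariate %r has one level; skipped", cov)
            continue
        idx = levels.index
        out.append(rank_test(s.loc[idx].to_numpy(), levels.to_numpy(),
                             mode="k-sample", covariate=cov))
    return out
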