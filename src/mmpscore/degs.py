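"""Moderated-t differential expression between consensus clusters.

Each cluster is contrasted against the rest of the cohort (one-vs-rest), so
every gene gets a signed log2 fold change per cluster — the direction later
needed to split genes into up/down signatures.  Gene-wise variances are
shrunk toward a pooled prior with the standard empirical-Bayes moments
estimator (scaled inverse-chi-square prior fit on log sample variances via
digamma/trigamma matching), the moderated t gets the augmented degrees of
freedom, and Benjamini-Hochberg adjustment runs jointly across all
gene x contrast tests.  A gene passes at the conventional thresholds
adjusted p < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_io import DataError, ExpressionMatrix

logger = logging.getLogger("mmpscore")

DEFAULT_P_ADJ = 0.05
DEFAULT_LFC = 1.0


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (the package's FDR convention)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s2)`` to its theoretical
    distribution under the hierarchical model; returns ``(d0, s0_squared)``
    where ``d0`` may be ``inf`` (no excess dispersion: complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderated_deg_table(
    expr: ExpressionMatrix,
    labels: pd.Series,
    p_adj_threshold: float = DEFAULT_P_ADJ,
    lfc_threshold: float = DEFAULT_LFC,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """One-vs-rest moderated-t tests for every gene and cluster.

    Parameters
    ----------
    expr
        Expression matrix (log2 scale).
    labels
        Per-sample cluster assignment covering ``expr``'s samples.
    prior_df
        Override the empirical-Bayes prior degrees of freedom; ``0`` recovers
        the ordinary pooled two-sample t exactly.

    Returns
    -------
    DataFrame with columns ``gene_id, contrast, log2fc, t, p, p_adj, passes``;
    BH adjustment spans all gene x contrast tests jointly.
    """
    labels = labels.reindex(expr.sample_ids)
    if labels.isna().any():
        raise DataError("labels do not cover all expression samples")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise DataError("need >=2 clusters for differential expression")
    X = expr.values.to_numpy()
    rows = []
    for c in clusters:
        in_mask = (labels == c).to_numpy()
        n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
        if n1 < 2 or n2 < 2:
            raise DataError(f"cluster {c!r} (or its complement) has < 2 samples")
        x1, x2 = X[:, in_mask], X[:, ~in_mask]
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, df)
        elif prior_df == 0:
            d0, s0_sq = 0.0, 1.0
        else:
            d0 = float(prior_df)
            _, s0_sq = fit_variance_prior(s2, df)
        if math.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = d0 + df
        lfc = m1 - m2
        denom = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, lfc / denom, 0.0)
        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.where(denom > 0, p, 1.0)  # zero-variance gene carries no signal
        rows.append(pd.DataFrame({
            "gene_id": expr.gene_ids,
            "contrast": f"cluster{c}_vs_rest",
            "log2fc": lfc,
            "t": t,
            "p": np.clip(p, 0.0, 1.0),
        }))
    table = pd.concat(rows, ignore_index=True)
    table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    table["passes"] = (table["p_adj"] < p_adj_threshold) & (table["log2fc"].abs() > lfc_threshold)
    n_pass = int(table.groupby("gene_id")["passes"].any().sum())
    logger.info("moderated_deg_table: %d gene(s) pass in >=1 contrast", n_pass)
    return table


def filter_degs(
    records: pd.DataFrame,
    p_adj_threshold: float = DEFAULT_P_ADJ,
    lfc_threshold: float = DEFAULT_LFC,
) -> set[str]:
    """Union over contrasts of genes passing the thresholds.

    Thresholds default to the printed convention (adjusted p < 0.05 and
    |log2FC| > 1) but can be loosened; loosening never shrinks the set.
    """
    if records.empty:
        return set()
    passes = (records["p_adj"] < p_adj_threshold) & (records["log2fc"].abs() > lfc_threshold)
    return set(records.loc[passes, "gene_id"])
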