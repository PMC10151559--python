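"""Signature construction and the PC1-difference prognostic score.

DEGs are split into two signatures by the sign of their Spearman correlation
with a prognosis-ordered ordinal cluster variable (clusters ranked best to
worst survival, so signature A collects risk genes).  Each signature is
reduced by Boruta, then summarized per sample by the first principal
component of its centered/scaled gene submatrix; the score is

    score_i = PC1A_i - PC1B_i

with each PC1 oriented so it correlates positively with the mean expression
of its signature's genes (the sign convention is load-bearing: it makes a
high score track the risk signature, so the low-score half of the median
split carries the better prognosis whenever the signatures are prognostic).
The fitted gene weights, means and scales are frozen so external cohorts are
*projected*, never refit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ClinicalTable, DataError, ExpressionMatrix
from .survival import km_estimate

logger = logging.getLogger("mmpscore")


@dataclass
class SignaturePair:
    """Up (A) and down (B) signature gene lists plus the cluster ordering used."""

    signature_A: list[str]
    signature_B: list[str]
    cluster_order: list  # best -> worst prognosis

    def __post_init__(self) -> None:
        if set(self.signature_A) & set(self.signature_B):
            raise DataError("signatures A and B overlap")


@dataclass
class SignatureLoadings:
    """Frozen PC1 model of one signature: per-gene weight, mean and scale."""

    genes: list[str]
    weights: np.ndarray
    means: np.ndarray
    scales: np.ndarray

    def transform(self, expr: ExpressionMatrix, min_overlap: float = 0.7) -> pd.Series:
        """Project samples onto the frozen PC1.

        Genes absent from ``expr`` contribute 0 after centering (imputation
        at the training mean); an overlap below ``min_overlap`` is an error.
        """
        present = [g for g in self.genes if g in expr.values.index]
        frac = len(present) / len(self.genes)
        if frac < min_overlap:
            missing = sorted(set(self.genes) - set(present))
            raise DataError(
                f"only {frac:.0%} of signature genes present "
                f"(threshold {min_overlap:.0%}); missing: {missing}"
            )
        pos = {g: i for i, g in enumerate(self.genes)}
        scores = np.zeros(expr.n_samples)
        for g in present:
            i = pos[g]
            z = (expr.values.loc[g].to_numpy() - self.means[i]) / self.scales[i]
            scores += self.weights[i] * z
        return pd.Series(scores, index=expr.sample_ids)

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureLoadings":
        return cls(
            genes=list(d["genes"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
        )


@dataclass
class ScoreModel:
    """The frozen scoring system: one PC1 model per signature."""

    loadings_A: SignatureLoadings
    loadings_B: SignatureLoadings

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"A": self.loadings_A.to_dict(), "B": self.loadings_B.to_dict()},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(SignatureLoadings.from_dict(d["A"]), SignatureLoadings.from_dict(d["B"]))


@dataclass
class ScoreTable:
    """Per-sample PC1A/PC1B/score/group plus the frozen model."""

    table: pd.DataFrame  # columns pc1_A, pc1_B, score, group
    model: ScoreModel = field(default=None)  # type: ignore[assignment]

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


def assign_signatures(
    expr: ExpressionMatrix,
    deg_genes: set[str],
    labels: pd.Series,
    clinical: ClinicalTable,
    endpoint: str = "OS",
) -> SignaturePair:
    """Split DEGs into signatures by correlation with prognosis-ordered clusters.

    Clusters are ordered best to worst by their Kaplan-Meier survival at the
    largest follow-up time common to all clusters; the ordinal therefore
    *increases with worse prognosis*.  Genes with positive Spearman
    correlation against that ordinal become signature A (risk genes),
    negative ones signature B; exact zeros are excluded (logged).
    """
    labels = labels.reindex(expr.sample_ids)
    if labels.isna().any():
        raise DataError("labels do not cover all expression samples")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise DataError("need >=2 clusters to order by prognosis")
    ep = clinical.endpoint(endpoint)

    # largest common follow-up: the shortest of the clusters' max times
    t_common = min(
        float(ep.loc[ep.index.intersection(labels[labels == c].index), "time"].max())
        for c in clusters
    )
    surv_at = {}
    for c in clusters:
        idx = ep.index.intersection(labels[labels == c].index)
        curve = km_estimate(ep.loc[idx, "time"].to_numpy(), ep.loc[idx, "event"].to_numpy())
        surv_at[c] = curve.survival_at(t_common)
    order = sorted(clusters, key=lambda c: -surv_at[c])  # best first
    badness = {c: rank for rank, c in enumerate(order)}
    ordinal = labels.map(badness).to_numpy(dtype=float)

    genes = [g for g in expr.gene_ids if g in deg_genes]
    sig_a, sig_b, excluded = [], [], []
    X = expr.values.loc[genes].to_numpy()
    for g, row in zip(genes, X):
        if np.all(row == row[0]):
            excluded.append(g)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = stats.spearmanr(row, ordinal).statistic
        if np.isnan(r) or r == 0:
            excluded.append(g)
        elif r > 0:
            sig_a.append(g)
        else:
            sig_b.append(g)
    if excluded:
        logger.info("assign_signatures: %d gene(s) with zero correlation excluded: %s",
                    len(excluded), excluded[:10])
    return SignaturePair(sig_a, sig_b, order)


def _fit_pc1(expr: ExpressionMatrix, genes: list[str]) -> tuple[SignatureLoadings, pd.Series]:
    sub = expr.values.loc[genes]
    X = sub.to_numpy().T  # samples x genes
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    if np.all(scales == 0):
        raise DataError("signature contains only constant genes")
    keep = scales > 0
    if not keep.all():
        logger.warning("fit_scores: dropping %d constant gene(s) from signature",
                       int((~keep).sum()))
    genes_k = [g for g, k in zip(genes, keep) if k]
    Z = (X[:, keep] - means[keep]) / scales[keep]
    # PC1 via SVD of the centered/scaled matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    w = vt[0]
    scores = Z @ w
    # orient: positive correlation with the signature's mean expression
    mean_profile = Z.mean(axis=1)
    if np.corrcoef(scores, mean_profile)[0, 1] < 0:
        w = -w
        scores = -scores
    loadings = SignatureLoadings(genes_k, w, means[keep], scales[keep])
    return loadings, pd.Series(scores, index=expr.sample_ids)


def fit_scores(expr: ExpressionMatrix, pair: SignaturePair) -> ScoreTable:
    """Fit the PC1-difference score on a discovery cohort.

    Both signatures must be non-empty after reduction.  Returns a
    :class:`ScoreTable` with the per-sample PC1A, PC1B, score = PC1A - PC1B,
    the median-split group, and the frozen loadings for projection.
    """
    if not pair.signature_A or not pair.signature_B:
        raise DataError("both signatures must be non-empty")
    load_a, pc1_a = _fit_pc1(expr, pair.signature_A)
    load_b, pc1_b = _fit_pc1(expr, pair.signature_B)
    score = pc1_a - pc1_b
    table = pd.DataFrame({
        "pc1_A": pc1_a, "pc1_B": pc1_b, "score": score,
        "group": median_split(score),
    })
    return ScoreTable(table, ScoreModel(load_a, load_b))


def median_split(scores: pd.Series | np.ndarray) -> pd.Series:
    """Dichotomize at the median: score > median -> ``high``, else ``low``."""
    s = pd.Series(scores)
    if len(s) < 2:
        raise DataError("median split needs >=2 samples")
    med = float(np.median(s.to_numpy()))
    groups = pd.Series(np.where(s.to_numpy() > med, "high", "low"), index=s.index,
                       name="group")
    if (groups == "low").all():
        logger.warning("median_split: all scores <= median (degenerate split)")
    return groups


def project_scores(
    new_expr: ExpressionMatrix,
    model: ScoreModel,
    min_overlap: float = 0.7,
) -> ScoreTable:
    """Score an external cohort with frozen loadings; median split recomputed
    within the new cohort.

    Missing signature genes are imputed at the frozen training mean (zero
    contribution after centering); each signature needs at least
    ``min_overlap`` of its genes present.
    """
    pc1_a = model.loadings_A.transform(new_expr, min_overlap)
    pc1_b = model.loadings_B.transform(new_expr, min_overlap)
    score = pc1_a - pc1_b
    table = pd.DataFrame({
        "pc1_A": pc1_a, "pc1_B": pc1_b, "score": score,
        "group": median_split(score),
    })
    return ScoreTable(table, model)
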