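"""Resampling-based consensus clustering with CDF/delta-area selection of K.

For each of ``reps`` resamples, a fraction ``p_item`` of samples is drawn
without replacement and a base clusterer (agglomerative, average linkage,
distance = 1 - Pearson correlation between samples) is run for every
candidate K.  The consensus matrix entry ``M_K[i, j]`` is the fraction of
resamples containing both *i* and *j* in which they co-cluster.  K is chosen
from the empirical CDF of consensus entries: the area under the CDF grows
with K, and the selected K is the last one whose *relative* area gain over
K-1 still exceeds a threshold (the reproducible surrogate for the usual
visual elbow read of the CDF/delta-area plots).

The resample index sets are drawn once and reused across K so the per-K
matrices are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .data_io import DataError, ExpressionMatrix, GeneSet

logger = logging.getLogger("mmpscore")


@dataclass
class ConsensusResult:
    """Per-K consensus matrices and the K-selection summary."""

    k_range: list[int]
    matrices: dict[int, np.ndarray]
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]]  # (values, F)
    areas: dict[int, float]
    delta_areas: dict[int, float]
    selected_k: int
    labels: pd.Series  # per-sample assignment in 1..selected_k
    sample_ids: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "k_range": self.k_range,
            "areas": {str(k): self.areas[k] for k in self.k_range},
            "delta_areas": {str(k): self.delta_areas[k] for k in self.k_range},
            "selected_k": self.selected_k,
            "cluster_sizes": self.labels.value_counts().sort_index().to_dict(),
        }


def correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between the columns of a genes x samples array.

    Zero-variance columns correlate with nothing; their off-diagonal
    distances are set to the maximum (1), except between identical constant
    columns, which get distance 0.
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = Xc / sd_safe
    corr = Z.T @ Z / X.shape[0]
    corr = np.clip(corr, -1.0, 1.0)
    D = 1.0 - corr
    if degenerate.any():
        D[degenerate, :] = 1.0
        D[:, degenerate] = 1.0
        idx = np.where(degenerate)[0]
        for i in idx:
            same = np.all(X[:, idx] == X[:, [i]], axis=0)
            D[i, idx[same]] = 0.0
            D[idx[same], i] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _base_cluster(D: np.ndarray, k: int) -> np.ndarray:
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                    linkage="average")
    return model.fit_predict(D)


def consensus_cdf_and_area(M: np.ndarray) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Empirical CDF of the off-diagonal upper-triangle consensus entries and
    its exact area over [0, 1].

    For an empirical CDF the integral reduces to ``1 - mean(entries)``; the
    step representation ``(values, F)`` is returned for plotting/QC.
    """
    n = M.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(M[iu])
    F = np.arange(1, vals.size + 1) / vals.size
    area = 1.0 - float(vals.mean())
    return (vals, F), area


def select_k(areas: dict[int, float], delta_threshold: float = 0.1) -> tuple[int, dict[int, float]]:
    """Select K from per-K CDF areas via the relative delta-area rule.

    ``delta(k_min) = A(k_min)``; for larger K, ``delta(K) = (A(K) -
    A(K-1)) / A(K-1)``.  The selected K is the largest one with
    ``delta(K) >= delta_threshold`` (ties toward smaller K are automatic:
    each K appears once).
    """
    ks = sorted(areas)
    if len(ks) < 2:
        raise ValueError("need >=2 candidate K values")
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        a_prev = areas[prev]
        gain = areas[k] - areas[prev]
        deltas[k] = gain / a_prev if a_prev > 0 else (math.inf if gain > 0 else 0.0)
    passing = [k for k in ks if deltas[k] >= delta_threshold]
    selected = max(passing) if passing else ks[0]
    return selected, deltas


def run_consensus(
    expr: ExpressionMatrix,
    genes: GeneSet | None = None,
    k_range: range | list[int] = range(2, 10),
    reps: int = 100,
    p_item: float = 0.8,
    seed: int = 0,
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Consensus-cluster the samples of ``expr`` over a gene subset.

    Parameters mirror the conventional defaults of resampling consensus
    clustering: 100 resamples at 80% sample fraction over K = 2..9.
    """
    if genes is not None:
        sub = expr.subset_genes(genes.genes)
    else:
        sub = expr
    X = sub.values.to_numpy()
    n = X.shape[1]
    if n < 3:
        raise DataError("consensus clustering needs >=3 samples")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not (0 < p_item <= 1):
        raise ValueError("p_item must be in (0, 1]")
    k_range = [int(k) for k in k_range]
    if any(k < 2 or k > n for k in k_range):
        raise ValueError(f"k_range must lie in [2, n_samples]; got {k_range}")

    D = correlation_distance(X)
    rng = np.random.default_rng(seed)
    m = math.ceil(p_item * n)
    draws = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(reps)]

    # pair bookkeeping shared across K
    both = np.zeros((n, n))
    for idx in draws:
        both[np.ix_(idx, idx)] += 1

    matrices: dict[int, np.ndarray] = {}
    for k in k_range:
        co = np.zeros((n, n))
        for idx in draws:
            lab = _base_cluster(D[np.ix_(idx, idx)], k)
            same = lab[:, None] == lab[None, :]
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(both > 0, co / np.maximum(both, 1), 0.0)
        never = int((both[np.triu_indices(n, k=1)] == 0).sum())
        if never:
            logger.info("run_consensus: K=%d: %d pair(s) never co-drawn (entry 0)", k, never)
        np.fill_diagonal(M, 1.0)
        matrices[k] = (M + M.T) / 2.0

    cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    areas: dict[int, float] = {}
    for k in k_range:
        cdfs[k], areas[k] = consensus_cdf_and_area(matrices[k])

    selected, deltas = select_k(areas, delta_threshold)

    # final labels from the consensus matrix (not any single base run)
    final = _base_cluster(1.0 - matrices[selected], selected)
    # deterministic relabel: clusters numbered 1..k by first occurrence
    order: dict[int, int] = {}
    for lab in final:
        if lab not in order:
            order[lab] = len(order) + 1
    labels = pd.Series([order[lab] for lab in final], index=sub.sample_ids,
                       name="cluster")

    return ConsensusResult(
        k_range=k_range,
        matrices=matrices,
        cdfs=cdfs,
        areas=areas,
        delta_areas=deltas,
        selected_k=selected,
        labels=labels,
        sample_ids=sub.sample_ids,
    )


def pca_projection(
    expr: ExpressionMatrix,
    genes: GeneSet | None = None,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """First two principal components of the scaled gene submatrix.

    Samples are observations; genes are centered and scaled to unit variance
    (constant genes dropped with a warning).  Returns a frame with columns
    ``PC1``, ``PC2`` and, when given, ``cluster`` — the QC projection used to
    eyeball the consensus classes.
    """
    sub = expr.subset_genes(genes.genes) if genes is not None else expr
    X = sub.values.to_numpy().T  # samples x genes
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("pca_projection: dropping %d constant gene(s)", int((~keep).sum()))
    if keep.sum() == 0:
        coords = np.zeros((X.shape[0], 2))
    else:
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        n_comp = min(2, Z.shape[1], Z.shape[0])
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(Z)
        coords = np.zeros((X.shape[0], 2))
        coords[:, :n_comp] = scores[:, :2]
    out = pd.DataFrame(coords, index=sub.sample_ids, columns=["PC1", "PC2"])
    if labels is not None:
        out["cluster"] = labels.reindex(out.index)
    return out
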