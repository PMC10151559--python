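"""Synthetic cohorts with planted structure for recovery testing.

The generator emulates the statistical shape of a bulk tumor expression
cohort as the pipeline assumes it:

* *cluster genes* carry a planted K-group mixture (per-gene, per-cluster
  Gaussian mean offsets scaled by ``cluster_separation``);
* a per-sample *latent prognostic factor* ``f`` equals the standardized
  ordinal group index plus Gaussian noise; *signature genes* load on it with
  ``+signature_effect`` (up genes) or ``-signature_effect`` (down genes);
* survival times are exponential with hazard ``h0 * exp(hazard_log_hr * f)``,
  with the baseline chosen so median survival at ``f = 0`` is 36 months, and
  uniform censoring thinned to approximately ``censor_rate``;
* mutation burden is Poisson with a per-group mean, variants spread over a
  fixed gene panel by a long-tailed multinomial;
* ordinal stage covariates (T, N, M, G, TNM) are quantile bins of a noisy
  copy of ``f``.

A single seed expands to per-component child seeds (``SeedSequence.spawn``)
so adding a component never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix, MutationMatrix

#: Baseline hazard: median exponential survival of 36 months at f = 0.
BASELINE_HAZARD = math.log(2) / 36.0

#: SD of the Gaussian noise added to the standardized group index to form
#: the latent factor.
LATENT_NOISE_SD = 0.5


@dataclass
class CohortSpec:
    """Parameters of a planted cohort.

    Defaults describe the regime the pipeline targets: a three-cluster
    mixture over a 45-gene curated panel, a moderately noisy prognostic
    factor, a hazard ratio of 2 per unit factor, and ~30% censoring.
    """

    n_samples: int = 300
    n_cluster_genes: int = 45
    n_signature_genes: int = 60
    n_noise_genes: int = 100
    k_true: int = 3
    cluster_separation: float = 2.5
    signature_effect: float = 1.0
    noise_sd: float = 0.5
    hazard_log_hr: float = math.log(2)
    censor_rate: float = 0.3
    mutation_burden_means: tuple[float, ...] = (8.0, 6.0, 4.0)
    n_mutation_genes: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_cluster_genes", "n_signature_genes",
                     "n_noise_genes", "k_true", "n_mutation_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if len(self.mutation_burden_means) != self.k_true:
            raise ValueError("mutation_burden_means must have one mean per cluster")


@dataclass
class SyntheticCohort:
    """Generated inputs plus the ground truth used to generate them."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationMatrix
    truth: dict = field(default_factory=dict)
    spec: CohortSpec | None = None


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a :class:`SyntheticCohort` (deterministic given ``spec.seed``)."""
    (rng_labels, rng_cluster, rng_latent, rng_sig, rng_noise,
     rng_surv, rng_mut, rng_stage) = _child_rngs(spec.seed, 8)

    n, k = spec.n_samples, spec.k_true
    # balanced groups, shuffled
    labels = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    rng_labels.shuffle(labels)
    samples = [f"S{i:04d}" for i in range(n)]

    # cluster genes: per-cluster Gaussian means with two equal-variance parts —
    # a severity gradient along the subtype index (random per-gene slope, shared
    # across genes, which the downstream signature construction assumes) and a
    # subtype-specific random offset that keeps the K groups mutually distinct
    gc = spec.n_cluster_genes
    z_c = (np.arange(k) - (k - 1) / 2.0)
    z_c = z_c / z_c.std() if k > 1 else z_c
    slopes = rng_cluster.standard_normal(gc)
    offsets = spec.cluster_separation / np.sqrt(2.0) * (
        np.outer(slopes, z_c) + rng_cluster.standard_normal((gc, k)))
    cluster_expr = offsets[:, labels] + spec.noise_sd * rng_cluster.standard_normal((gc, n))

    # latent prognostic factor: standardized ordinal group index + noise
    z = (labels - labels.mean()) / labels.std()
    f = z + LATENT_NOISE_SD * rng_latent.standard_normal(n)

    gs = spec.n_signature_genes
    n_up = gs // 2
    sig_sign = np.ones(gs)
    sig_sign[n_up:] = -1.0
    sig_expr = (sig_sign[:, None] * spec.signature_effect * f[None, :]
                + spec.noise_sd * rng_sig.standard_normal((gs, n)))

    noise_expr = spec.noise_sd * rng_noise.standard_normal((spec.n_noise_genes, n))

    cluster_genes = [f"CG{i:03d}" for i in range(gc)]
    up_genes = [f"SIGUP{i:03d}" for i in range(n_up)]
    down_genes = [f"SIGDN{i:03d}" for i in range(gs - n_up)]
    noise_genes = [f"NG{i:03d}" for i in range(spec.n_noise_genes)]
    values = pd.DataFrame(
        np.vstack([cluster_expr, sig_expr, noise_expr]),
        index=cluster_genes + up_genes + down_genes + noise_genes,
        columns=samples,
    )
    expression = ExpressionMatrix(values)

    # survival: exponential PH in f, censoring by thinning
    hazard = BASELINE_HAZARD * np.exp(spec.hazard_log_hr * f)
    t_event = rng_surv.exponential(1.0 / hazard)
    censored = rng_surv.random(n) < spec.censor_rate
    time = np.where(censored, rng_surv.random(n) * t_event, t_event)
    event = (~censored).astype(int)
    clin = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for ep in ("OS", "PFS", "DSS", "DFS"):
        clin[f"{ep}_time"] = time
        clin[f"{ep}_event"] = event

    # ordinal stages: quantile bins of a noisy copy of f
    stage_noisy = f + 0.75 * rng_stage.standard_normal(n)
    for cov, levels in (("T", 4), ("N", 4), ("M", 2), ("G", 3), ("TNM", 4)):
        qs = np.quantile(stage_noisy, np.linspace(0, 1, levels + 1)[1:-1])
        clin[cov] = np.digitize(stage_noisy, qs) + 1
    clinical = ClinicalTable(clin)

    # mutations: Poisson burden per group, variants multinomial over a panel
    means = np.asarray(spec.mutation_burden_means, dtype=float)
    burden = rng_mut.poisson(means[labels])
    panel = [f"MUT{i:03d}" for i in range(spec.n_mutation_genes)]
    probs = 1.0 / np.arange(1, spec.n_mutation_genes + 1)  # long-tailed panel
    probs /= probs.sum()
    mut_values = np.zeros((spec.n_mutation_genes, n), dtype=int)
    for i in range(n):
        if burden[i] > 0:
            counts = rng_mut.multinomial(burden[i], probs)
            mut_values[:, i] = (counts > 0).astype(int)
    mutations = MutationMatrix(
        pd.DataFrame(mut_values, index=panel, columns=samples),
        pd.Series(burden, index=samples, dtype=int),
    )

    truth = {
        "cluster_labels": pd.Series(labels, index=samples, name="cluster"),
        "latent_factor": pd.Series(f, index=samples, name="latent_factor"),
        "up_genes": list(up_genes),
        "down_genes": list(down_genes),
        "cluster_genes": list(cluster_genes),
        "hazard_log_hr": spec.hazard_log_hr,
    }
    return SyntheticCohort(expression, clinical, mutations, truth, spec)


def generate_drug_panel(
    n_lines: int,
    n_genes: int,
    n_causal: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, np.ndarray]:
    """Reference drug panel: cell-line expression and a linear log-IC50.

    The first ``n_causal`` genes carry nonzero coefficients; log-IC50 is their
    linear combination plus ``N(0, noise_sd^2)`` noise.  Returns the
    expression matrix (genes x lines), the per-line log-IC50 and the true
    coefficient vector (length ``n_genes``).
    """
    if n_causal > n_genes:
        raise ValueError("n_causal must be <= n_genes")
    rng_x, rng_beta, rng_eps = _child_rngs(seed, 3)
    X = rng_x.standard_normal((n_lines, n_genes))
    beta = np.zeros(n_genes)
    beta[:n_causal] = rng_beta.uniform(0.5, 2.0, n_causal) * rng_beta.choice([-1, 1], n_causal)
    y = X @ beta + noise_sd * rng_eps.standard_normal(n_lines)
    lines = [f"LINE{i:03d}" for i in range(n_lines)]
    genes = [f"DG{i:03d}" for i in range(n_genes)]
    expr = ExpressionMatrix(pd.DataFrame(X.T, index=genes, columns=lines))
    return expr, pd.Series(y, index=lines, name="log_ic50"), beta


def make_planted_classification(
    n_samples: int = 500,
    n_features: int = 50,
    n_informative: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels driven by the sum of the first ``n_informative`` features.

    A strong, clean planted signal used for feature-selection recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    X = rng.standard_normal((n_samples, n_features))
    score = X[:, :n_informative].sum(axis=1)
    y = (score > np.median(score)).astype(int)
    return X, y
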