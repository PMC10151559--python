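"""Configuration-driven end-to-end orchestration.

``run_pipeline`` composes the stages in analysis order — input reading and
sample alignment, consensus clustering of the curated gene set, one-vs-rest
differential expression, signature construction with Boruta reduction, score
fitting and median dichotomization, per-endpoint survival analysis of the
score groups, and the association battery — writing per-stage tables plus a
machine-readable JSON report.  Any stage failure aborts with the stage name
and cause; outputs written by earlier stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .associations import (
    clinicopath_association,
    mutation_burden_compare,
    per_gene_mutation_assoc,
)
from .boruta import boruta_select
from .consensus import pca_projection, run_consensus
from .data_io import DataError
from .degs import filter_degs, moderated_deg_table
from .scoring import SignaturePair, assign_signatures, fit_scores
from .survival import (
    DEFAULT_HORIZONS,
    cox_univariate,
    km_estimate,
    logrank_test,
    time_dependent_auc,
)

logger = logging.getLogger("mmpscore")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name (exit codes 3/4)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All file paths, thresholds and seeds of one pipeline run."""

    expression: str
    clinical: str
    gene_sets: str
    outdir: str
    gene_set_names: list[str] = field(default_factory=list)
    mutations: str | None = None
    covariates: str | None = None
    k_range: list[int] = field(default_factory=lambda: list(range(2, 10)))
    reps: int = 100
    p_item: float = 0.8
    delta_threshold: float = 0.1
    deg_p_adj: float = 0.05
    deg_lfc: float = 1.0
    boruta_max_iter: int = 50
    boruta_alpha: float = 0.05
    endpoints: list[str] = field(default_factory=lambda: ["OS", "PFS", "DSS", "DFS"])
    horizons: list[float] = field(default_factory=lambda: list(DEFAULT_HORIZONS))
    min_mutated: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = [k for k in ("expression", "clinical", "gene_sets", "outdir")
                   if k not in raw]
        if missing:
            raise ConfigError(f"missing required config key(s): {missing}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("expression", "clinical", "gene_sets"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} file does not exist: {p}")
        for key in ("mutations", "covariates"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{key} file does not exist: {p}")
        if self.deg_p_adj <= 0 or self.deg_lfc < 0:
            raise ConfigError("DEG thresholds must be positive")
        if not (0 < self.p_item <= 1):
            raise ConfigError("p_item must be in (0, 1]")
        if self.reps < 2:
            raise ConfigError("reps must be >= 2")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the JSON report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": dataclasses.asdict(config)}

    # --- data_io ----------------------------------------------------------
    stage = "data_io"
    try:
        expr = data_io.read_expression_matrix(config.expression)
        clinical = data_io.read_clinical_table(config.clinical)
        sets = data_io.read_gene_sets_gmt(config.gene_sets)
        if config.gene_set_names:
            chosen = [s for s in sets if s.name in config.gene_set_names]
            if len(chosen) != len(config.gene_set_names):
                found = {s.name for s in chosen}
                raise DataError(
                    f"gene set(s) not in GMT: {sorted(set(config.gene_set_names) - found)}"
                )
        else:
            chosen = sets
        gene_set = data_io.union_gene_sets(chosen)
        mutations = None
        if config.mutations:
            mutations = data_io.mutation_matrix_from_maf(
                config.mutations, samples=expr.sample_ids
            )
        expr, clinical = data_io.align_samples(expr, clinical)
        report["n_samples"] = expr.n_samples
        report["n_genes"] = expr.n_genes
        report["gene_set_size"] = len(gene_set.genes)
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, err) from err

    # --- consensus clustering --------------------------------------------
    stage = "consensus_clustering"
    try:
        cons = run_consensus(
            expr, gene_set, k_range=config.k_range, reps=config.reps,
            p_item=config.p_item, seed=config.seed,
            delta_threshold=config.delta_threshold,
        )
        cons.labels.to_csv(outdir / "cluster_labels.tsv", sep="\t")
        with open(outdir / "consensus_summary.json", "w") as fh:
            json.dump(_jsonable(cons.summary()), fh, indent=1)
        proj = pca_projection(expr, gene_set, cons.labels)
        proj.to_csv(outdir / "pca_projection.tsv", sep="\t")
        report["selected_k"] = cons.selected_k
        report["cluster_sizes"] = cons.labels.value_counts().sort_index().to_dict()
        report["consensus_areas"] = cons.areas
        report["consensus_delta_areas"] = cons.delta_areas
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- differential expression -----------------------------------------
    stage = "differential_expression"
    try:
        deg_table = moderated_deg_table(
            expr, cons.labels, p_adj_threshold=config.deg_p_adj,
            lfc_threshold=config.deg_lfc,
        )
        deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
        deg_genes = filter_degs(deg_table, config.deg_p_adj, config.deg_lfc)
        report["n_degs"] = len(deg_genes)
        if not deg_genes:
            raise DataError("no DEGs pass the thresholds")
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- signature scoring ------------------------------------------------
    stage = "signature_scoring"
    try:
        pair = assign_signatures(expr, deg_genes, cons.labels, clinical,
                                 endpoint=config.endpoints[0])
        sig_genes = pair.signature_A + pair.signature_B
        X = expr.values.loc[sig_genes].to_numpy().T
        sel = boruta_select(
            pd.DataFrame(X, columns=sig_genes), cons.labels.to_numpy(),
            max_iter=config.boruta_max_iter, alpha=config.boruta_alpha,
            seed=config.seed,
        )
        keep = set(sel.confirmed)  # tentative excluded from scoring
        reduced = SignaturePair(
            [g for g in pair.signature_A if g in keep],
            [g for g in pair.signature_B if g in keep],
            pair.cluster_order,
        )
        if not reduced.signature_A or not reduced.signature_B:
            logger.warning("signature_scoring: Boruta emptied a signature; "
                           "falling back to unreduced signatures")
            reduced = pair
        score_table = fit_scores(expr, reduced)
        score_table.table.to_csv(outdir / "score_table.tsv", sep="\t")
        score_table.model.to_json(outdir / "score_model.json")
        report["signature_sizes"] = {
            "A": len(reduced.signature_A), "B": len(reduced.signature_B),
            "A_pre_boruta": len(pair.signature_A), "B_pre_boruta": len(pair.signature_B),
        }
        report["boruta"] = {
            "confirmed": len(sel.confirmed), "rejected": len(sel.rejected),
            "tentative": len(sel.tentative), "iterations": sel.n_iterations,
        }
        report["score_group_sizes"] = score_table.groups.value_counts().to_dict()
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- survival analysis ------------------------------------------------
    stage = "survival_analysis"
    try:
        surv_report: dict = {}
        groups = score_table.groups
        for ep in config.endpoints:
            if ep not in clinical.endpoints:
                logger.warning("survival_analysis: endpoint %s absent; skipped", ep)
                continue
            tab = clinical.endpoint(ep)
            common = tab.index.intersection(groups.index)
            tab = tab.loc[common]
            g = groups.loc[common]
            lr = logrank_test(tab["time"], tab["event"], g)
            cox = cox_univariate(tab["time"], tab["event"],
                                 score_table.scores.loc[common])
            aucs = time_dependent_auc(tab["time"], tab["event"],
                                      score_table.scores.loc[common],
                                      horizons=config.horizons)
            for grp in ("high", "low"):
                idx = g[g == grp].index
                curve = km_estimate(tab.loc[idx, "time"], tab.loc[idx, "event"], ep)
                curve.as_frame().to_csv(outdir / f"km_{ep}_{grp}.tsv", sep="\t",
                                        index=False)
            surv_report[ep] = {
                "logrank_chi2": lr.chi2, "logrank_p": lr.p,
                "cox_beta": cox.beta, "cox_se": cox.se, "cox_p": cox.p,
                "cox_flagged": cox.flagged,
                "auc": {str(h): aucs.auc[h] for h in aucs.horizons},
            }
        report["survival"] = surv_report
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- associations -----------------------------------------------------
    stage = "association_stats"
    try:
        assoc_report: dict = {}
        stage_cols = clinical.stage_covariates
        if stage_cols:
            comps = clinicopath_association(
                score_table.scores, clinical.data[stage_cols]
            )
            assoc_report["clinicopathological"] = {
                c.covariate: {"statistic": c.statistic, "p": c.p, "stars": c.stars}
                for c in comps
            }
        if mutations is not None:
            common = [s for s in groups.index if s in mutations.sample_ids]
            bc = mutation_burden_compare(mutations.burden.loc[common],
                                         groups.loc[common])
            assoc_report["mutation_burden"] = {
                "statistic": bc.statistic, "p": bc.p,
                "medians": bc.medians, "stars": bc.stars,
            }
            per_gene = per_gene_mutation_assoc(
                mutations, groups, min_mutated=config.min_mutated
            )
            pd.DataFrame([{
                "gene_id": r.gene_id, "odds_ratio": r.odds_ratio, "beta": r.beta,
                "se": r.se, "p": r.p, "q": r.q, "corrected": r.corrected,
            } for r in per_gene]).to_csv(outdir / "mutation_assoc.tsv", sep="\t",
                                         index=False)
            assoc_report["n_genes_tested"] = len(per_gene)
        report["associations"] = assoc_report
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    logger.info("run_pipeline: report written to %s", outdir / "report.json")
    return report
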