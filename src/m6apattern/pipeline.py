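"""End-to-end orchestration: patterns -> DEGs -> gene clusters -> score ->
survival / OSAHS / TMB associations.

The run is a pure function of (input files, config, seed): every stage
derives its randomness from the single config seed, and the bundle is
written with a machine-readable manifest recording the seed and all
thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cc
from . import de
from . import mutation as mut_mod
from . import scoring
from . import survival as surv
from .config import PipelineConfig
from .datatypes import ClinicalTable, ExpressionMatrix
from .io import read_clinical, read_expression, read_gmt, read_mutations
from .reference import M6A_REGULATORS
from .simulate import SimulationParams, simulate_cohort, stage_rng

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    pattern_labels: pd.Series
    pattern_k: int
    gene_cluster_labels: pd.Series
    gene_cluster_k: int
    degs: list[str]
    model: scoring.SignatureModel
    score_table: scoring.ScoreTable
    survival_stats: dict
    associations: dict
    manifest: dict
    enrichment: pd.DataFrame | None = None
    tmb: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        params = SimulationParams(
            n_samples=config.sim_n_samples,
            delta=config.sim_delta,
            hazard_beta=config.sim_hazard_beta,
            censoring_rate=config.sim_censoring_rate,
            seed=config.seed,
        )
        expr, clinical, mutations, _truth = simulate_cohort(params)
        return expr, clinical, mutations, None
    if not config.expression or not config.clinical:
        raise StageError("inputs", "config must set expression and clinical paths, or simulate: true")
    expr = read_expression(config.expression, unit=config.expression_unit)
    try:
        clinical = read_clinical(config.clinical)
    except ValueError as err:
        raise StageError("inputs", f"clinical table invalid: {err}") from err
    mutations = read_mutations(config.mutations) if config.mutations else None
    sets = read_gmt(config.gmt) if config.gmt else None
    return expr, clinical, mutations, sets


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the result bundle."""
    expr, clinical, mutations, gene_sets = _load_inputs(config)
    clinical = clinical.aligned_to(expr.sample_ids)
    if clinical.event.sum() < 1:
        raise StageError("inputs", "no events in the clinical data")

    regulators = [g for g in (config.regulators or M6A_REGULATORS) if g in expr.gene_ids]
    if len(regulators) < 2:
        raise StageError("patterns", "fewer than 2 regulator genes present in the matrix")

    # stage: m6A patterns (consensus clustering of regulator expression)
    try:
        pat = cc.consensus_cluster(
            expr, regulators,
            k_range=range(config.pattern_k_min, config.pattern_k_max + 1),
            n_iter=config.consensus_iterations,
            frac=config.consensus_fraction,
            seed=int(stage_rng(config.seed, "patterns").integers(2 ** 31)),
            delta_threshold=config.delta_area_threshold,
        )
    except ValueError as err:
        raise StageError("patterns", str(err)) from err
    pattern_labels = pd.Series(pat.labels, index=expr.sample_ids, name="pattern")

    # stage: phenotype DEGs between patterns
    try:
        if pat.chosen_k == 2:
            deres = de.moderated_de(expr, pattern_labels.to_numpy())
            degs = de.select_degs(deres, config.deg_mode)
        else:
            degs, _ = de.multiclass_degs(expr, pattern_labels.to_numpy(), config.deg_mode)
    except ValueError as err:
        raise StageError("degs", str(err)) from err
    degs = [g for g in degs if g not in regulators]
    if not degs:
        raise StageError("degs", "no differentially expressed gene passes the thresholds")

    # stage: gene clusters (consensus clustering of samples on the DEGs)
    try:
        gclust = cc.consensus_cluster(
            expr, degs,
            k_range=range(config.genecluster_k_min, config.genecluster_k_max + 1),
            n_iter=config.consensus_iterations,
            frac=config.consensus_fraction,
            seed=int(stage_rng(config.seed, "gene_clusters").integers(2 ** 31)),
            delta_threshold=config.delta_area_threshold,
        )
    except ValueError as err:
        raise StageError("gene_clusters", str(err)) from err
    gene_cluster_labels = pd.Series(gclust.labels, index=expr.sample_ids, name="gene_cluster")

    # stage: m6A score (Cox screen + PCA; bootstrap formula selection)
    try:
        if config.score_formula == "auto":
            sel = scoring.bootstrap_select_formula(
                degs, expr, clinical,
                n_iter=config.bootstrap_iterations,
                split=config.bootstrap_split,
                seed=int(stage_rng(config.seed, "bootstrap").integers(2 ** 31)),
                p_threshold=config.cox_p_threshold,
            )
            formula = sel.formula
            bootstrap_summary = {"mean_cindex": sel.mean_cindex,
                                 "n_completed": sel.n_completed, "n_skipped": sel.n_skipped}
        else:
            formula = config.score_formula
            bootstrap_summary = None
        model = scoring.fit_signature(degs, expr, clinical, config.cox_p_threshold)
        model.formula = formula
        scores = scoring.score_samples(model, expr)
    except (ValueError, KeyError) as err:
        raise StageError("score", str(err)) from err

    # stage: survival stratification at the maximally selected cutpoint
    try:
        cut = surv.max_rank_cutpoint(scores.to_numpy(), clinical.time, clinical.event,
                                     minprop=config.cutpoint_minprop)
    except ValueError as err:
        raise StageError("survival", str(err)) from err
    groups = pd.Series(cut.groups(scores.to_numpy()), index=scores.index, name="score_group")
    score_table = scoring.ScoreTable(scores, groups, cut.cutpoint)
    lr = surv.logrank_test(clinical.time, clinical.event, groups.to_numpy())
    km = {
        g: surv.km_estimate(clinical.time[groups.to_numpy() == g],
                            clinical.event[groups.to_numpy() == g])
        for g in ("high", "low")
    }
    survival_stats = {
        "cutpoint": cut.cutpoint,
        "logrank_chi2": lr.statistic,
        "logrank_p": lr.p_value,
        "five_year_survival": {g: km[g].at(5 * 365.25) for g in km},
        "median_survival": {g: km[g].median() for g in km},
        "cindex": surv.harrell_cindex(scores.to_numpy(), clinical.time, clinical.event),
    }

    # stage: clinical associations
    associations: dict = {}
    if "osahs" in clinical.data.columns and clinical.data["osahs"].notna().any():
        osahs = clinical.data["osahs"].astype(int)
        table = pd.crosstab(groups, osahs)
        odds, p = surv.group_compare(table.to_numpy(), None, "fisher")
        prevalence = {g: float(osahs[groups == g].mean()) for g in ("high", "low")}
        auc, ci = surv.auc_mannwhitney(scores.to_numpy(), osahs.to_numpy())
        associations["osahs"] = {"prevalence": prevalence, "fisher_p": p,
                                 "odds_ratio": odds, "auc": auc, "auc_ci": ci}
    tmb = None
    if mutations is not None and len(mutations):
        tmb = mut_mod.compute_tmb(mutations, expr.sample_ids, mode=config.tmb_mode,
                                  exome_mb=config.exome_mb)
        rho, p = surv.spearman(tmb.to_numpy(), scores.to_numpy())
        tmb_groups = mut_mod.tmb_median_split(tmb)
        strata, strata_lr = mut_mod.joint_strata(groups, tmb_groups,
                                                 clinical.time, clinical.event)
        summary = mut_mod.mutation_summary(mutations, n_cohort=expr.n_samples)
        associations["tmb"] = {
            "spearman_rho": rho, "spearman_p": p,
            "relevant": abs(rho) >= config.rho_threshold and p < config.assoc_p_threshold,
            "joint_strata_chi2": strata_lr.statistic,
            "joint_strata_df": strata_lr.df,
            "joint_strata_p": strata_lr.p_value,
            "top_mutated_genes": summary.index.tolist(),
        }

    manifest = {"config": config.as_dict(), "seed": config.seed,
                "n_samples": int(expr.n_samples), "n_genes": int(expr.n_genes),
                "pattern_k": int(pat.chosen_k), "gene_cluster_k": int(gclust.chosen_k),
                "n_degs": len(degs), "n_signature_genes": len(model.genes),
                "score_formula": model.formula,
                "bootstrap": bootstrap_summary}

    result = PipelineResult(
        pattern_labels=pattern_labels,
        pattern_k=int(pat.chosen_k),
        gene_cluster_labels=gene_cluster_labels,
        gene_cluster_k=int(gclust.chosen_k),
        degs=degs,
        model=model,
        score_table=score_table,
        survival_stats=survival_stats,
        associations=associations,
        manifest=manifest,
        tmb=tmb,
    )
    if config.outdir:
        write_bundle(result, Path(config.outdir))
    return result


def write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = pd.DataFrame({
        "pattern": result.pattern_labels,
        "gene_cluster": result.gene_cluster_labels,
    })
    labels.to_csv(outdir / "cluster_labels.tsv", sep="\t", index_label="sample_id")
    st = pd.DataFrame({
        "m6a_score": result.score_table.scores,
        "score_group": result.score_table.group,
    })
    st.to_csv(outdir / "score_table.tsv", sep="\t", index_label="sample_id",
              float_format="%.10g")
    pd.Series(result.degs, name="gene").to_csv(outdir / "degs.tsv", sep="\t", index=False)
    model = result.model
    model_json = {
        "genes": model.genes,
        "formula": model.formula,
        "cox_coef": model.cox_coef.round(10).to_dict(),
        "mean": model.mean.round(10).to_dict(),
        "sd": model.sd.round(10).to_dict(),
        "w1": model.w1.round(10).to_dict(),
        "w2": model.w2.round(10).to_dict(),
    }
    (outdir / "signature_model.json").write_text(json.dumps(model_json, indent=1))
    stats = {"survival": result.survival_stats, "associations": result.associations}
    (outdir / "stats.json").write_text(json.dumps(stats, indent=1, default=float))
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(result.manifest, default=float)), fh)
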