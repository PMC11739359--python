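"""End-to-end orchestration of the biomarker discovery pipeline.

Stages, in the order they run on a cohort:

1. preprocess — quantile normalization + batch adjustment;
2. discover — per-timepoint moderated differential expression, two-timepoint
   intersection and filter cascade → stable up/down signature;
3. hub selection on interaction networks among the up genes;
4. ratio scoring — hub / down-gene ratio, AUROC with bootstrap CI, Youden
   threshold per timepoint;
5. qPCR platform transfer — simulate/ingest Cq plates for the two marker
   genes, efficiency-corrected IRC-calibrated quantification, ratio
   threshold recomputed on the qPCR scale;
6. risk stratification — lactate x ratio three-tier groups, mortality
   table, KM curves, log-rank tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .config import PipelineConfig
from .diffexp import DEGTable, fit_group_comparison
from .network import GeneNetwork, network_from_edges, rank_hubs, select_hub
from .preprocess import combat_adjust, quantile_normalize
from .qpcr import quantify, ratio_from_relquant
from .ratio import RatioScoreResult, evaluate_ratio, youden_threshold
from .signature import SignatureSet, build_signature
from .stratify import RiskGroupResult, RiskRule, stratify_cohort
from .synthetic import (
    D1,
    D23,
    ExpressionCohort,
    generate_cohort,
    generate_networks,
    generate_qpcr_plates,
)

log = logging.getLogger("sepsisratio.pipeline")


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one cohort."""

    cohort: ExpressionCohort
    deg: dict[str, DEGTable]
    signature: SignatureSet
    hub_gene: str | None
    down_gene: str | None
    hub_ranking: pd.DataFrame | None
    array_ratio: dict[str, RatioScoreResult] = field(default_factory=dict)
    qpcr_ratio: pd.Series | None = None
    qpcr_threshold: float | None = None
    qpcr_eval: dict[str, RatioScoreResult] = field(default_factory=dict)
    risk: dict[str, RiskGroupResult] = field(default_factory=dict)


def preprocess_cohort(
    cohort: ExpressionCohort, protect_outcome: bool = False
) -> ExpressionCohort:
    """Quantile normalization followed by empirical-Bayes batch adjustment."""
    qn = quantile_normalize(cohort.matrix)
    covariates = cohort.meta["outcome"] if protect_outcome else None
    n_batches = cohort.meta["batch"].nunique()
    if n_batches > 1:
        adjusted, _ = combat_adjust(qn, cohort.meta["batch"], covariates=covariates)
    else:
        adjusted = qn
    return ExpressionCohort(adjusted, cohort.meta.copy())


def discover_signature(
    cohort: ExpressionCohort, config: PipelineConfig
) -> tuple[dict[str, DEGTable], SignatureSet]:
    deg = {
        tp: fit_group_comparison(cohort, tp, p_de=config.p_de) for tp in (D1, D23)
    }
    sig = build_signature(
        deg[D1],
        deg[D23],
        fc_log2_min=config.fc_log2_min,
        q_max=config.q_max,
        linear_fc_min=config.linear_fc_min,
        b_posterior_min=config.b_posterior_min,
    )
    log.info(
        "signature: %d up, %d down (%d sign conflicts dropped)",
        len(sig.up_genes),
        len(sig.down_genes),
        len(sig.dropped_sign_conflicts),
    )
    return deg, sig


def choose_markers(
    cohort: ExpressionCohort,
    signature: SignatureSet,
    networks: list[GeneNetwork],
    config: PipelineConfig,
) -> tuple[str, str, pd.DataFrame]:
    """Hub gene among the up set; best-discriminating partner among the down set.

    The down-gene partner is chosen by the higher mean two-timepoint AUROC of
    the hub/down ratio, mirroring the head-to-head comparison of candidate
    ratios; ties break lexicographically.
    """
    ranking = rank_hubs(signature.up_genes, networks)
    hub = select_hub(ranking)
    if not signature.down_genes:
        raise ValueError("no down-regulated genes to pair with the hub")
    best: tuple[float, str] | None = None
    for dg in sorted(signature.down_genes):
        aucs = []
        for tp in (D1, D23):
            sub = cohort.subset_timepoint(tp)
            res = evaluate_ratio(
                sub.matrix.loc[hub],
                sub.matrix.loc[dg],
                sub.meta["outcome"],
                n_boot=1,  # AUROC only; the full CI comes later
                seed=config.seed,
            )
            aucs.append(res.auroc)
        mean_auc = float(np.mean(aucs))
        if best is None or mean_auc > best[0] + 1e-12:
            best = (mean_auc, dg)
    return hub, best[1], ranking


def score_array_ratio(
    cohort: ExpressionCohort, up_gene: str, down_gene: str, config: PipelineConfig
) -> dict[str, RatioScoreResult]:
    out = {}
    for tp in (D1, D23):
        sub = cohort.subset_timepoint(tp)
        out[tp] = evaluate_ratio(
            sub.matrix.loc[up_gene],
            sub.matrix.loc[down_gene],
            sub.meta["outcome"],
            up_gene=up_gene,
            down_gene=down_gene,
            timepoint=tp,
            n_boot=config.n_bootstrap,
            seed=config.seed,
        )
        log.info(
            "%s array ratio AUROC %.3f (95%% CI %.3f-%.3f)",
            tp,
            out[tp].auroc,
            out[tp].ci_lo,
            out[tp].ci_hi,
        )
    return out


def qpcr_transfer(
    cq_table: pd.DataFrame,
    cohort: ExpressionCohort,
    up_gene: str,
    down_gene: str,
    config: PipelineConfig,
) -> tuple[pd.Series, float, dict[str, RatioScoreResult]]:
    """Quantify plates, compute the qPCR-scale ratio and its Youden threshold."""
    rel, _curves = quantify(cq_table, efficiency_corrected=config.efficiency_corrected)
    ratio = ratio_from_relquant(rel, up_gene, down_gene)
    ratio = ratio.loc[[s for s in ratio.index if s in cohort.meta.index]]
    labels = cohort.meta.loc[ratio.index, "outcome"]
    if config.ratio_cutoff is None:
        thr, _, _ = youden_threshold(ratio.to_numpy(), labels.to_numpy())
    else:
        thr = float(config.ratio_cutoff)
    evals = {}
    for tp in (D1, D23):
        mask = cohort.meta.loc[ratio.index, "timepoint"] == tp
        if mask.sum() == 0:
            continue
        idx = ratio.index[mask]
        evals[tp] = evaluate_ratio(
            np.log2(ratio.loc[idx]),
            pd.Series(0.0, index=idx),
            labels.loc[idx],
            up_gene=up_gene,
            down_gene=down_gene,
            timepoint=tp,
            n_boot=config.n_bootstrap,
            seed=config.seed,
            threshold=thr,
        )
    return ratio, thr, evals


def stratify_by_risk(
    cohort: ExpressionCohort,
    ratio: pd.Series,
    threshold: float,
    config: PipelineConfig,
) -> dict[str, RiskGroupResult]:
    """Three-tier risk groups per timepoint from lactate + per-patient ratio."""
    rule = RiskRule(lactate_cutoff=config.lactate_cutoff, ratio_cutoff=threshold)
    patients = cohort.patient_table()
    out = {}
    for tp in (D1, D23):
        sub = cohort.meta[cohort.meta["timepoint"] == tp]
        per_patient = pd.Series(
            {row["patient_id"]: ratio[sid] for sid, row in sub.iterrows() if sid in ratio.index}
        )
        if per_patient.empty:
            continue
        out[tp] = stratify_cohort(
            patients.loc[per_patient.index],
            per_patient,
            rule=rule,
            censor_day=config.censor_day,
            timepoint=tp,
        )
    return out


def run_all(config: PipelineConfig) -> PipelineResult:
    """Simulate a cohort and run every stage end to end."""
    cohort_cfg = config.cohort.replace(seed=config.seed)
    cohort, truth = generate_cohort(cohort_cfg)
    networks = [
        network_from_edges(e, name=f"net{i + 1}")
        for i, e in enumerate(generate_networks(truth, cohort_cfg))
    ]
    pre = preprocess_cohort(cohort, protect_outcome=config.protect_outcome)
    deg, sig = discover_signature(pre, config)
    hub, down, ranking = choose_markers(pre, sig, networks, config)
    array_eval = score_array_ratio(pre, hub, down, config)
    cq = generate_qpcr_plates(cohort, [hub, down], cohort_cfg)
    ratio, thr, qpcr_eval = qpcr_transfer(cq, cohort, hub, down, config)
    risk = stratify_by_risk(cohort, ratio, thr, config)
    return PipelineResult(
        cohort=pre,
        deg=deg,
        signature=sig,
        hub_gene=hub,
        down_gene=down,
        hub_ranking=ranking,
        array_ratio=array_eval,
        qpcr_ratio=ratio,
        qpcr_threshold=thr,
        qpcr_eval=qpcr_eval,
        risk=risk,
    )


def summarize(result: PipelineResult) -> dict:
    """JSON-serializable run summary (signature, AUROCs, threshold, risk groups)."""
    out = {
        "signature": {
            "n_up": len(result.signature.up_genes),
            "n_down": len(result.signature.down_genes),
            "up_genes": result.signature.up_genes,
            "down_genes": result.signature.down_genes,
        },
        "hub_gene": result.hub_gene,
        "down_gene": result.down_gene,
        "qpcr_threshold": result.qpcr_threshold,
        "array_ratio": {},
        "qpcr_ratio": {},
        "risk": {},
    }
    for tp, res in result.array_ratio.items():
        out["array_ratio"][tp] = {
            "auroc": res.auroc,
            "ci": [res.ci_lo, res.ci_hi],
            "youden_threshold": res.youden_threshold,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
        }
    for tp, res in result.qpcr_eval.items():
        out["qpcr_ratio"][tp] = {
            "auroc": res.auroc,
            "ci": [res.ci_lo, res.ci_hi],
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
        }
    for tp, rg in result.risk.items():
        out["risk"][tp] = {
            "groups": {
                g: {
                    "n": int(rg.mortality.loc[g, "n"]),
                    "deaths": int(rg.mortality.loc[g, "deaths"]),
                    "mortality_percent": (
                        None
                        if rg.mortality.loc[g, "mortality_percent"] is None
                        else int(rg.mortality.loc[g, "mortality_percent"])
                    ),
                }
                for g in rg.mortality.index
            },
            "association_chi2_p": rg.mortality.attrs["chi2_p"],
            "overall_logrank_p": rg.overall_logrank[2],
            "pairwise_logrank": rg.pairwise.to_dict(orient="records"),
        }
    return out


def write_report(result: PipelineResult, out_dir) -> None:
    """Emit the run summary as JSON plus TSV tables (signature, KM coordinates)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summarize(result), fh, indent=2, default=float)
    result.signature.provenance.to_csv(out / "signature.tsv", sep="\t")
    if result.hub_ranking is not None:
        result.hub_ranking.to_csv(out / "hub_ranking.tsv", sep="\t")
    for tp, rg in result.risk.items():
        rg.mortality.to_csv(out / f"risk_groups_{tp}.tsv", sep="\t")
        for g, km in rg.km_curves.items():
            km.to_csv(out / f"km_{tp}_{g}.tsv", sep="\t")
    if result.qpcr_ratio is not None:
        result.qpcr_ratio.rename("ratio").to_csv(out / "qpcr_ratio.tsv", sep="\t")
    sio.write_expression(result.cohort.matrix, out / "expression_preprocessed.tsv")
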