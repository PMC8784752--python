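"""End-to-end orchestration of the pair-signature analysis.

Stages (each available individually from the corresponding module):
clinical filtering -> log2(x+1) -> biotype split -> immune co-expression
screen -> tumor/normal differential expression -> pair-score matrix +
frequency filter -> univariate Cox -> cross-validated Lasso-Cox ->
stepwise multivariate Cox -> risk scores -> 3-year ROC cutoff ->
dichotomization -> Kaplan-Meier / log-rank validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .assoc import km_estimate, log_rank
from .io import (
    ClinicalTable,
    DataError,
    ExpressionMatrix,
    GeneAnnotation,
    SampleGroups,
    filter_clinical,
    log_transform,
    split_by_biotype,
)
from .pairs import PairScoreMatrix, build_pair_matrix, frequency_filter, pair_scores_for
from .screen import differential_expression, select_de_genes, select_immune_lncrnas
from .signature import (
    RiskProfile,
    SignatureModel,
    compute_risk_scores,
    dichotomize,
    lasso_cox_cv,
    select_cutoff,
    stepwise_multivariate_cox,
    td_roc,
    univariate_cox_screen,
)

logger = logging.getLogger("irlpair")

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage (defaults as published)."""

    min_days: float = 30.0
    max_missing_frac: float = 0.25
    r_thresh: float = 0.4
    corr_p_thresh: float = 0.001
    corr_method: str = "pearson"
    corr_signed: bool = False
    logfc_thresh: float = 1.0
    fdr_thresh: float = 0.05
    freq_low: float = 0.2
    freq_high: float = 0.8
    uni_p_thresh: float = 0.05
    lasso_folds: int = 10
    lasso_rule: str = "min"
    horizon_years: float = 3.0
    roc_horizons_years: tuple[float, ...] = (1.0, 3.0, 5.0)
    cutoff_rule: str = "youden"
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    clinical: ClinicalTable
    irlnc_ids: list[str] = field(default_factory=list)
    corr_records: pd.DataFrame | None = None
    de_table: pd.DataFrame | None = None
    de_ids: list[str] = field(default_factory=list)
    pair_matrix: PairScoreMatrix | None = None
    univariate_table: pd.DataFrame | None = None
    univariate_retained: list[str] = field(default_factory=list)
    lasso_selected: list[str] = field(default_factory=list)
    model: SignatureModel | None = None
    risk: RiskProfile | None = None
    rocs: dict = field(default_factory=dict)
    cutoff: float | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    km_curves: dict | None = None
    stopped_at: str | None = None  # stage name if the cascade emptied out


def run_pipeline(
    expression: ExpressionMatrix,
    annotation: GeneAnnotation,
    clinical: ClinicalTable,
    immune_symbols: list[str],
    groups: SampleGroups,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full signature pipeline on a linear-scale expression cohort.

    Stops gracefully (``stopped_at`` set) if a selection stage empties the
    candidate set — a real possibility on null data — rather than raising.
    """
    clin = filter_clinical(clinical, config.min_days, config.max_missing_frac)
    result = PipelineResult(config=config, clinical=clin)

    em_log = log_transform(expression)
    lnc_em, mrna_em = split_by_biotype(em_log, annotation)
    immune_ids = annotation.ids_for_symbols(immune_symbols, biotype="protein_coding")
    immune_ids = [g for g in immune_ids if g in set(mrna_em.gene_ids)]
    if not immune_ids:
        raise DataError("no immune genes found in the expression matrix")

    irlnc_ids, corr = select_immune_lncrnas(
        lnc_em, mrna_em.subset_genes(immune_ids),
        r_thresh=config.r_thresh, p_thresh=config.corr_p_thresh,
        method=config.corr_method, signed=config.corr_signed,
    )
    result.irlnc_ids, result.corr_records = irlnc_ids, corr
    if not irlnc_ids:
        result.stopped_at = "immune_screen"
        return result

    de_table = differential_expression(lnc_em.subset_genes(irlnc_ids), groups)
    de_ids = select_de_genes(de_table, config.logfc_thresh, config.fdr_thresh)
    result.de_table, result.de_ids = de_table, de_ids
    if len(de_ids) < 2:
        result.stopped_at = "differential_expression"
        return result

    tumor = [s for s in groups.samples("tumor")
             if s in set(expression.sample_ids) and s in set(clin.sample_ids)]
    if not tumor:
        raise DataError("no tumor samples shared by expression and clinical data")
    pm = frequency_filter(
        build_pair_matrix(expression.subset_genes(de_ids), sample_ids=tumor),
        config.freq_low, config.freq_high,
    )
    result.pair_matrix = pm
    if pm.n_pairs == 0:
        result.stopped_at = "frequency_filter"
        return result

    clin_t = clin.subset(tumor)
    retained, uni_table = univariate_cox_screen(pm, clin_t, config.uni_p_thresh)
    result.univariate_table, result.univariate_retained = uni_table, retained
    if len(retained) < 2:
        result.stopped_at = "univariate_screen"
        return result

    pm_uni = PairScoreMatrix(pm.scores.loc[retained])
    lasso = lasso_cox_cv(pm_uni, clin_t, folds=config.lasso_folds,
                         seed=config.seed, rule=config.lasso_rule)
    result.lasso_selected = lasso.selected
    if not lasso.selected:
        result.stopped_at = "lasso"
        return result

    pm_sel = PairScoreMatrix(pm.scores.loc[lasso.selected])
    model = stepwise_multivariate_cox(pm_sel, clin_t)
    if not model.pairs:
        result.stopped_at = "stepwise"
        result.model = model
        return result
    model.metadata.update({
        "seed": config.seed,
        "thresholds": asdict(config),
        "lasso_alpha": lasso.best_alpha,
        "cutoff_rule": config.cutoff_rule,
    })
    result.model = model

    profile = compute_risk_scores(model, pm)
    time, event = clin_t.time, clin_t.event
    for years in config.roc_horizons_years:
        result.rocs[years] = td_roc(profile.risk.to_numpy(), time, event,
                                    years * DAYS_PER_YEAR)
    roc_main = result.rocs.get(config.horizon_years) or td_roc(
        profile.risk.to_numpy(), time, event,
        config.horizon_years * DAYS_PER_YEAR)
    if not roc_main.defined:
        result.stopped_at = "roc"
        result.risk = profile
        return result
    cutoff = select_cutoff(roc_main)
    model.cutoff = cutoff
    result.cutoff = cutoff
    profile = dichotomize(profile, cutoff)
    result.risk = profile

    labels = profile.group.to_numpy()
    if len(np.unique(labels)) == 2:
        result.km_curves = km_estimate(time, event, labels)
        result.logrank_chi2, result.logrank_p = log_rank(time, event, labels)
    else:
        result.stopped_at = "dichotomize"
    return result


def score_samples(model: SignatureModel, expression: ExpressionMatrix,
                  sample_ids=None) -> RiskProfile:
    """Score (possibly unseen) samples with a fitted signature.

    Pair scores are recomputed from expression, so any cohort measured on
    any platform with the signature's genes can be scored; the stored
    cutoff, if any, is applied.
    """
    if sample_ids is not None:
        expression = expression.subset_samples(sample_ids)
    pm = pair_scores_for(model.pairs, expression)
    profile = compute_risk_scores(model, pm)
    if model.cutoff is not None:
        profile = dichotomize(profile, model.cutoff)
    return profile
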