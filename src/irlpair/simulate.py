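"""Synthetic tumor/normal cohort generator with known ground truth.

The generator emulates the statistical structure the pair-signature pipeline
assumes, so every stage has a recoverable answer:

* a single per-sample immune latent factor ties immune genes and a subset of
  lncRNAs together (co-expression screen has planted positives);
* a subset of the immune-linked lncRNAs receives a tumor-vs-normal log2
  shift (differential-expression screen has planted positives);
* survival of each tumor sample follows an exponential proportional-hazards
  model on a small set of planted within-sample pair indicators, with
  uniform right censoring (the signature fit has planted positives with
  known log-hazard coefficients).

On the log2 scale a gene value is ``mu_g + loading_g * f_s + N(0, noise_sd)``
with ``f_s ~ N(0,1)``, so the population correlation between two genes that
both load on the factor is ``loading^2 / (loading^2 + noise_sd^2)``
(0.8 at the defaults). Linear-scale expression is ``2^log2value - 1``
floored at 0, which makes ``log2(x + 1)`` recover the latent log2 value.

Planted pair genes share a common log2 mean, so each planted indicator is
close to Bernoulli(0.5) and survives the 20-80% frequency filter by design.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    DataError,
    ExpressionMatrix,
    GeneAnnotation,
    SampleGroups,
    read_annotation,
    read_clinical,
    read_expression,
    read_gene_list,
    read_groups,
    write_annotation,
    write_clinical,
    write_expression,
    write_gene_list,
    write_groups,
)
from .pairs import PairDef

COHORT_FILES = (
    "expression.tsv",
    "annotation.tsv",
    "clinical.tsv",
    "groups.tsv",
    "immune_genes.txt",
    "truth.json",
)

#: common log2 mean given to every DE lncRNA so planted pairs are ~Bernoulli(0.5)
DE_LOG2_MEAN = 4.0


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters (defaults define the study conditions).

    Sample sizes and gene counts are scaled to desk size while keeping the
    proportions of a bulk tumor/normal RNA-seq cohort: a few hundred tumors,
    an order of magnitude fewer normals, ~10-year follow-up with uniform
    censoring and a baseline hazard giving roughly half observed events.
    """

    n_tumor: int = 400
    n_normal: int = 50
    n_lnc: int = 200
    n_immune_genes: int = 60
    n_other_mrna: int = 100
    n_immune_linked: int = 80
    n_de: int = 60
    de_log2fc: float = 2.0
    n_planted_pairs: int = 5
    planted_betas: tuple[float, ...] = (1.0, 0.875, 0.75, 0.625, 0.5)
    baseline_hazard: float = 2.5e-4  # events per day
    censor_max_days: float = 3650.0
    noise_sd: float = 0.5
    latent_loading: float = 1.0
    m_stage_missing_frac: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lnc", "n_immune_genes",
                     "n_other_mrna", "n_immune_linked", "n_de"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_planted_pairs < 0:
            raise ConfigError("n_planted_pairs must be >= 0")
        if self.n_immune_linked > self.n_lnc:
            raise ConfigError("n_immune_linked exceeds n_lnc")
        if self.n_de > self.n_immune_linked:
            raise ConfigError("n_de exceeds n_immune_linked")
        max_pairs = math.comb(self.n_de, 2)
        if self.n_planted_pairs > max_pairs:
            raise ConfigError(
                f"n_planted_pairs {self.n_planted_pairs} exceeds C(n_de,2)={max_pairs}"
            )
        if len(self.planted_betas) != self.n_planted_pairs:
            raise ConfigError("planted_betas length must equal n_planted_pairs")
        if self.censor_max_days <= 30:
            raise ConfigError("censor_max_days must exceed 30")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ConfigError("noise_sd and baseline_hazard must be positive")


@dataclass
class CohortTruth:
    """Ground truth planted by the generator."""

    immune_linked_ids: list[str]
    de_ids: list[str]
    planted_pairs: list[PairDef]
    planted_betas: list[float]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # linear scale, tumor + normal columns
    annotation: GeneAnnotation
    groups: SampleGroups
    clinical: ClinicalTable  # tumor samples only
    immune_symbols: list[str]
    truth: CohortTruth
    config: SimulationConfig | None = None


def event_fraction_null(baseline_hazard: float, censor_max_days: float) -> float:
    """Analytic event fraction for Exp(hazard) survival vs U(0, c) censoring."""
    lc = baseline_hazard * censor_max_days
    return 1.0 - (1.0 - math.exp(-lc)) / lc


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one fully seeded cohort from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    lnc_ids = _gene_ids("LNC", config.n_lnc)
    irg_ids = _gene_ids("IRG", config.n_immune_genes)
    pcg_ids = _gene_ids("PCG", config.n_other_mrna)
    gene_ids = lnc_ids + irg_ids + pcg_ids
    n_genes = len(gene_ids)

    tumor_ids = [f"TUM{i + 1:04d}" for i in range(config.n_tumor)]
    normal_ids = [f"NRM{i + 1:04d}" for i in range(config.n_normal)]
    sample_ids = tumor_ids + normal_ids
    n_samples = len(sample_ids)

    linked_ids = lnc_ids[: config.n_immune_linked]
    de_ids = linked_ids[: config.n_de]

    means = rng.uniform(2.0, 6.0, size=n_genes)
    means[: config.n_de] = DE_LOG2_MEAN  # DE lncRNAs share a mean (pair design)

    loadings = np.zeros(n_genes)
    loadings[: config.n_immune_linked] = config.latent_loading  # linked lncRNAs
    loadings[config.n_lnc: config.n_lnc + config.n_immune_genes] = config.latent_loading

    factor = rng.standard_normal(n_samples)
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    log2 = means[:, None] + loadings[:, None] * factor[None, :] + noise
    log2[: config.n_de, : config.n_tumor] += config.de_log2fc

    linear = np.maximum(np.exp2(log2) - 1.0, 0.0)
    expr = pd.DataFrame(linear, index=gene_ids, columns=sample_ids)
    expr.index.name = "gene_id"

    # planted pairs: disjoint draws from the DE set when possible, canonical
    # (lexicographically ordered) orientation
    pairs: list[PairDef] = []
    if config.n_planted_pairs:
        if 2 * config.n_planted_pairs <= config.n_de:
            perm = rng.permutation(config.n_de)
            chosen = [
                (de_ids[perm[2 * j]], de_ids[perm[2 * j + 1]])
                for j in range(config.n_planted_pairs)
            ]
        else:
            combos = list(itertools.combinations(de_ids, 2))
            idx = rng.choice(len(combos), size=config.n_planted_pairs, replace=False)
            chosen = [combos[i] for i in idx]
        pairs = [PairDef.canonical(a, b) for a, b in chosen]

    betas = np.asarray(config.planted_betas, dtype=float)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    lp = np.zeros(config.n_tumor)
    for pair, beta in zip(pairs, betas):
        z = linear[gene_pos[pair.gene_a], : config.n_tumor] > \
            linear[gene_pos[pair.gene_b], : config.n_tumor]
        lp += beta * z
    hazard = config.baseline_hazard * np.exp(lp)

    t_true = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, config.censor_max_days, size=config.n_tumor)
    time = np.maximum(np.minimum(t_true, t_cens), 1.0)
    event = (t_true <= t_cens).astype(int)

    stage = rng.choice(["I", "II", "III", "IV"], size=config.n_tumor,
                       p=[0.5, 0.25, 0.15, 0.1])
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], size=config.n_tumor,
                         p=[0.3, 0.4, 0.2, 0.1])
    n_stage = rng.choice(["N0", "N1", "N2"], size=config.n_tumor,
                         p=[0.6, 0.25, 0.15])
    m_stage = rng.choice(["M0", "M1"], size=config.n_tumor, p=[0.85, 0.15])
    m_stage = pd.array(m_stage, dtype="object")
    m_missing = rng.random(config.n_tumor) < config.m_stage_missing_frac
    m_stage[m_missing] = np.nan
    age = np.clip(np.round(rng.normal(65.0, 10.0, size=config.n_tumor)), 30, 90)
    gender = rng.choice(["F", "M"], size=config.n_tumor)

    clinical = ClinicalTable(pd.DataFrame({
        "time_days": time,
        "event": event,
        "stage": stage,
        "t_stage": t_stage,
        "n_stage": n_stage,
        "m_stage": m_stage,
        "age": age,
        "gender": gender,
    }, index=pd.Index(tumor_ids, name="sample_id")))

    annotation = GeneAnnotation(pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": gene_ids,
        "biotype": (["lncRNA"] * config.n_lnc
                    + ["protein_coding"] * (config.n_immune_genes
                                            + config.n_other_mrna)),
    }))
    groups = SampleGroups(pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
        index=pd.Index(sample_ids, name="sample_id"), name="group",
    ))
    truth = CohortTruth(
        immune_linked_ids=list(linked_ids),
        de_ids=list(de_ids),
        planted_pairs=pairs,
        planted_betas=[float(b) for b in betas],
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(expr, "linear"),
        annotation=annotation,
        groups=groups,
        clinical=clinical,
        immune_symbols=list(irg_ids),
        truth=truth,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir, overwrite: bool = False) -> dict:
    """Write the cohort as TSV/text files plus a JSON truth sidecar."""
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, name) for name in COHORT_FILES}
    if not overwrite:
        clash = [p for p in paths.values() if os.path.exists(p)]
        if clash:
            raise FileExistsError(
                f"refusing to overwrite {clash[0]} (pass overwrite=True)"
            )
    write_expression(cohort.expression, paths["expression.tsv"])
    write_annotation(cohort.annotation, paths["annotation.tsv"])
    write_clinical(cohort.clinical, paths["clinical.tsv"])
    write_groups(cohort.groups, paths["groups.tsv"])
    write_gene_list(cohort.immune_symbols, paths["immune_genes.txt"])
    truth = {
        "immune_linked_ids": cohort.truth.immune_linked_ids,
        "de_ids": cohort.truth.de_ids,
        "planted_pairs": [[p.gene_a, p.gene_b] for p in cohort.truth.planted_pairs],
        "planted_betas": cohort.truth.planted_betas,
        "config": asdict(cohort.config) if cohort.config else None,
    }
    with open(paths["truth.json"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def read_cohort(indir) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    paths = {name: os.path.join(indir, name) for name in COHORT_FILES}
    with open(paths["truth.json"], encoding="utf-8") as fh:
        truth_raw = json.load(fh)
    cfg = truth_raw.get("config")
    truth = CohortTruth(
        immune_linked_ids=truth_raw["immune_linked_ids"],
        de_ids=truth_raw["de_ids"],
        planted_pairs=[PairDef.canonical(a, b) for a, b in truth_raw["planted_pairs"]],
        planted_betas=truth_raw["planted_betas"],
    )
    return SyntheticCohort(
        expression=read_expression(paths["expression.tsv"]),
        annotation=read_annotation(paths["annotation.tsv"]),
        groups=read_groups(paths["groups.tsv"]),
        clinical=read_clinical(paths["clinical.tsv"]),
        immune_symbols=read_gene_list(paths["immune_genes.txt"]),
        truth=truth,
        config=SimulationConfig(**{**cfg, "planted_betas": tuple(cfg["planted_betas"])})
        if cfg else None,
    )
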