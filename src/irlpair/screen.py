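"""Immune-related lncRNA screening and differential expression.

Two screens run in sequence on ``log2(x+1)`` expression:

1. co-expression with a curated immune-gene list: a lncRNA is called
   immune-related iff at least one immune gene shows |r| > 0.4 with
   p < 0.001 (strict inequalities; the correlation sign is not restricted
   because negative immune co-regulation is still immune-related);
2. tumor-vs-normal differential expression of the immune-related lncRNAs:
   Welch two-sample t-test per gene with Benjamini-Hochberg adjustment,
   retaining |log2 fold change| > 1 and FDR < 0.05.

The t-test is a deliberate, documented surrogate for a moderated linear
model: at the group sizes this pipeline targets (tens of samples per arm)
variance moderation is immaterial, and the plain test keeps the screen
self-contained.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DataError, ExpressionMatrix, LOG2P1, SampleGroups

logger = logging.getLogger("irlpair")

#: p-values that underflow to 0 are reported as the smallest positive float
#: so -log10 transforms stay finite
MIN_P = float(np.nextafter(0.0, 1.0))


class PearsonResult(NamedTuple):
    r: float
    p: float
    degenerate: bool = False


def pearson_test(x, y) -> PearsonResult:
    """Pearson r with the two-sided t-based p-value.

    Constant input yields a degenerate record (r = nan, p = 1) rather than
    an exception, so vectorized screens can proceed past flat genes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson_test requires equal-length vectors")
    n = x.size
    if n < 3:
        raise DataError("pearson_test requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(np.nan, 1.0, True)
    r, p = stats.pearsonr(x, y)
    return PearsonResult(float(r), max(float(p), MIN_P), False)


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between A (a x n) and B (b x n)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A * A).sum(axis=1))
    sb = np.sqrt((B * B).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A @ B.T) / np.outer(sa, sb)
    r[~np.isfinite(r)] = np.nan  # constant rows -> degenerate
    return np.clip(r, -1.0, 1.0)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p = np.where(np.isnan(r), 1.0, p)       # degenerate -> p = 1
    p = np.where(np.abs(r) >= 1.0, 0.0, p)  # |r| = 1 -> t infinite
    return np.maximum(p, MIN_P)


def select_immune_lncrnas(
    lnc_em: ExpressionMatrix,
    imm_em: ExpressionMatrix,
    r_thresh: float = 0.4,
    p_thresh: float = 0.001,
    method: str = "pearson",
    signed: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Immune-related lncRNAs by co-expression with immune genes.

    A lncRNA is retained iff at least one immune gene satisfies
    ``|r| > r_thresh`` and ``p < p_thresh`` (both strict). With
    ``signed=True`` only positive correlations count. ``method`` may be
    ``"pearson"`` or ``"spearman"`` (Pearson on ranks, same t p-value).

    Returns the retained lncRNA ids (input order) and a DataFrame of all
    qualifying (lnc_id, immune_gene_id, r, p) records.
    """
    if lnc_em.scale_tag != LOG2P1 or imm_em.scale_tag != LOG2P1:
        raise DataError("co-expression screen expects log2p1-scale matrices")
    if lnc_em.sample_ids != imm_em.sample_ids:
        if set(lnc_em.sample_ids) != set(imm_em.sample_ids):
            raise DataError("lncRNA and immune-gene matrices cover different samples")
        imm_em = imm_em.subset_samples(lnc_em.sample_ids)
    n = len(lnc_em.sample_ids)
    if n < 3:
        raise DataError("co-expression screen requires >= 3 samples")
    L = lnc_em.values.to_numpy()
    M = imm_em.values.to_numpy()
    if method == "spearman":
        L = stats.rankdata(L, axis=1)
        M = stats.rankdata(M, axis=1)
    elif method != "pearson":
        raise DataError(f"unknown correlation method {method!r}")
    r = _corr_matrix(L, M)
    p = _corr_pvalues(r, n)
    effect = r if signed else np.abs(r)
    with np.errstate(invalid="ignore"):
        hit = (effect > r_thresh) & (p < p_thresh)
    hit &= ~np.isnan(r)
    retained = [g for g, row in zip(lnc_em.gene_ids, hit) if row.any()]
    li, mi = np.nonzero(hit)
    records = pd.DataFrame({
        "lnc_id": np.asarray(lnc_em.gene_ids)[li],
        "immune_gene_id": np.asarray(imm_em.gene_ids)[mi],
        "r": r[li, mi],
        "p": p[li, mi],
    })
    logger.info("immune co-expression screen retained %d of %d lncRNAs",
                len(retained), len(lnc_em.gene_ids))
    return retained, records


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("bh_adjust expects a non-empty 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    em: ExpressionMatrix, groups: SampleGroups
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal Welch t-test on log2p1 values.

    Returns a DataFrame indexed by gene_id with columns ``log_fc``
    (mean tumor - mean normal), ``p``, ``fdr`` and ``direction``.
    """
    if em.scale_tag != LOG2P1:
        raise DataError("differential expression expects a log2p1-scale matrix")
    tumor = [s for s in em.sample_ids if groups.assignments.get(s) == "tumor"]
    normal = [s for s in em.sample_ids if groups.assignments.get(s) == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise DataError("each group needs at least 2 samples")
    T = em.values[tumor].to_numpy()
    N = em.values[normal].to_numpy()
    log_fc = T.mean(axis=1) - N.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(T, N, axis=1, equal_var=False)
    # zero pooled variance: equal means -> no evidence (p=1); unequal -> p->0
    p = np.where(np.isnan(p), np.where(log_fc == 0, 1.0, MIN_P), p)
    p = np.maximum(p, MIN_P)
    fdr = bh_adjust(p)
    out = pd.DataFrame({
        "log_fc": log_fc,
        "p": p,
        "fdr": fdr,
        "direction": np.where(log_fc >= 0, "up", "down"),
    }, index=pd.Index(em.gene_ids, name="gene_id"))
    return out


def select_de_genes(
    de_table: pd.DataFrame, logfc_thresh: float = 1.0, fdr_thresh: float = 0.05
) -> list[str]:
    """Gene ids with |log_fc| > logfc_thresh and fdr < fdr_thresh (strict)."""
    mask = (de_table["log_fc"].abs() > logfc_thresh) & (de_table["fdr"] < fdr_thresh)
    return list(de_table.index[mask])
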