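"""Survival validation and association of risk with clinical/external features.

Covers Kaplan-Meier curves and the two-group log-rank test for the risk
dichotomy, chi-square association of risk group with categorical clinical
variables, rank-based comparison of the continuous risk score across
clinical strata, generic association of risk with user-supplied
sample x feature tables (immune-cell fractions, checkpoint-gene expression,
per-drug IC50 — all computed by external tools and consumed here as plain
feature tables), and univariate/multivariate Cox fits testing whether the
risk score predicts survival independently of clinical covariates.

Between-group comparisons use the Mann-Whitney rank-sum test: the high and
low risk groups are independent samples, so the paired signed-rank variant
does not apply. Raw and Benjamini-Hochberg adjusted p-values are both
reported; the default significance flag uses raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ClinicalTable, DataError
from .screen import bh_adjust
from .signature import CoxFitResult, RiskProfile, fit_cox

logger = logging.getLogger("irlpair")

STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (s[0] > 1 + 1e-12 or (np.diff(s) > 1e-12).any()
                       or (s < -1e-12).any()):
            raise DataError("survival curve must start at 1 and be non-increasing")


def km_estimate(time, event, labels) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group label."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    curves: dict[str, KMCurve] = {}
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():
            raise DataError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[str(g)] = KMCurve(
            group=str(g),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].to_numpy(dtype=float),
        )
    return curves


def log_rank(time, event, labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    Zero total variance (e.g. no events shared across risk sets) yields
    (nan, nan) rather than an exception.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise DataError(f"log-rank needs exactly two groups, got {len(groups)}")
    if (labels == groups[0]).sum() == 0 or (labels == groups[1]).sum() == 0:
        raise DataError("log-rank needs two non-empty groups")
    if event.sum() < 1:
        raise DataError("log-rank needs at least one event")
    res = multivariate_logrank_test(time, labels, event)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        logger.warning("log-rank: zero variance, result undefined")
        return float("nan"), float("nan")
    return chi2, p


def chi_square_assoc(labels, covariate) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square (no continuity correction) between two categoricals."""
    tab = pd.crosstab(pd.Series(labels, name="group"),
                      pd.Series(covariate, name="covariate"))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DataError("chi-square requires at least a 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DataError("degenerate margins in contingency table")
    chi2, p, _, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning("chi-square: %d cells with expected count < 5",
                       int((expected < 5).sum()))
    return float(chi2), float(p), tab


def rank_sum_compare(values, labels) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two independent groups.

    Exact enumeration when both groups have <= 20 untied observations,
    otherwise the tie-corrected normal approximation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise DataError(f"rank-sum needs exactly two groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise DataError("rank-sum needs two non-empty groups")
    has_ties = len(np.unique(values)) < values.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def associate_features(
    profile: RiskProfile,
    features: pd.DataFrame,
    method: str = "spearman_vs_score",
    min_overlap_frac: float = 0.5,
    sig_thresh: float = 0.05,
) -> pd.DataFrame:
    """Associate risk with each column of a sample x feature table.

    ``spearman_vs_score``: Spearman rho of feature vs risk score with the
    t-approximation p-value. ``rank_sum_vs_group``: Mann-Whitney U of the
    feature between high and low risk groups. One record per feature with
    raw p, BH-adjusted p, a sign/direction and a raw-p significance flag.
    """
    common = profile.table.index.intersection(features.index)
    if len(common) == 0:
        raise DataError("no overlapping samples between risk profile and features")
    if len(common) < 3:
        raise DataError("feature association requires >= 3 overlapping samples")
    if len(common) < min_overlap_frac * len(profile.table):
        logger.warning("feature table covers only %d/%d risk-profiled samples",
                       len(common), len(profile.table))
    feats = features.loc[common]
    records = []
    for col in feats.columns:
        vals = pd.to_numeric(feats[col], errors="coerce")
        ok = vals.notna()
        if ok.sum() < 3:
            records.append((col, np.nan, np.nan, "na"))
            continue
        if method == "spearman_vs_score":
            rho, p = stats.spearmanr(profile.risk.loc[common][ok], vals[ok])
            records.append((col, float(rho), float(p),
                            "positive" if rho >= 0 else "negative"))
        elif method == "rank_sum_vs_group":
            grp = profile.group.loc[common][ok]
            if grp.nunique() < 2:
                records.append((col, np.nan, np.nan, "na"))
                continue
            u, p = rank_sum_compare(vals[ok].to_numpy(), grp.to_numpy())
            med_hi = vals[ok][grp == "high"].median()
            med_lo = vals[ok][grp == "low"].median()
            records.append((col, float(u), float(p),
                            "higher_in_high" if med_hi >= med_lo else "higher_in_low"))
        else:
            raise DataError(f"unknown association method {method!r}")
    out = pd.DataFrame(records, columns=["feature_id", "statistic", "p", "direction"])
    out["statistic_kind"] = ("spearman_rho" if method == "spearman_vs_score"
                             else "rank_sum")
    valid = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["p_adj"] = adj
    out["significant"] = out["p"] < sig_thresh
    return out


def encode_clinical(
    clin: ClinicalTable,
    covariates=("age", "gender", "stage", "t_stage", "n_stage", "m_stage"),
) -> pd.DataFrame:
    """Numeric covariate encoding for Cox fits.

    Stage-like variables are encoded ordinally (I-IV -> 1-4, T1-T4 -> 1-4,
    N0-N2 -> 0-2, M0/M1 -> 0/1), gender as an indicator (M = 1), age as-is.
    Only covariates present in the table are returned.
    """
    tab = clin.table
    out: dict[str, pd.Series] = {}
    for cov in covariates:
        if cov not in tab.columns:
            continue
        col = tab[cov]
        if cov == "age":
            out[cov] = pd.to_numeric(col, errors="coerce")
        elif cov == "gender":
            out[cov] = col.map({"M": 1.0, "F": 0.0, "male": 1.0, "female": 0.0})
        elif cov == "stage":
            out[cov] = col.map(STAGE_CODES).astype(float)
        else:  # t/n/m stage: strip the letter prefix
            out[cov] = pd.to_numeric(
                col.astype("string").str.replace(r"^[TNMtnm]", "", regex=True),
                errors="coerce")
    return pd.DataFrame(out, index=tab.index)


def _collinear_sets(X: pd.DataFrame) -> list[str]:
    """Columns involved in (near-)linear dependence, by QR diagnostics."""
    A = X.to_numpy(dtype=float)
    A = (A - A.mean(axis=0)) / np.where(A.std(axis=0) == 0, 1, A.std(axis=0))
    _, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [c for c, b in zip(X.columns, bad) if b]


@dataclass
class IndependenceResult:
    univariate: pd.DataFrame
    multivariate: CoxFitResult | None
    collinear: list[str]


def cox_independence(
    risk_scores: pd.Series, clin: ClinicalTable, covariates=None
) -> IndependenceResult:
    """Uni- and multivariate Cox fits of risk score plus clinical covariates.

    Returns per-covariate single-variable fits (forest-table layout), the
    joint fit, and a list of collinear covariates (joint fit skipped and
    flagged when linear dependence is detected).
    """
    common = clin.table.index.intersection(risk_scores.index)
    if len(common) == 0:
        raise DataError("no overlap between risk scores and clinical table")
    clin = clin.subset(list(common))
    enc = encode_clinical(clin) if covariates is None else covariates.loc[common]
    X = enc.copy()
    X.insert(0, "risk_score", risk_scores.loc[common])
    X = X.dropna(axis=1, how="all")
    keep_rows = X.notna().all(axis=1)
    X = X[keep_rows]
    time = clin.table.loc[X.index, "time_days"].to_numpy(dtype=float)
    event = clin.table.loc[X.index, "event"].to_numpy(dtype=int)

    rows = []
    for col in X.columns:
        try:
            res = fit_cox(X[[col]], time, event)
            lo, hi = res.ci95
            rows.append((col, res.beta[0], res.hr[0], lo[0], hi[0],
                         res.p[0], res.converged))
        except DataError as exc:
            logger.warning("univariate Cox for %s failed: %s", col, exc)
            rows.append((col, np.nan, np.nan, np.nan, np.nan, np.nan, False))
    uni = pd.DataFrame(rows, columns=["covariate", "beta", "hr", "ci_low",
                                      "ci_high", "p", "converged"])

    collinear = _collinear_sets(X)
    multi = None
    if collinear:
        logger.warning("collinear covariates, joint fit skipped: %s", collinear)
    else:
        multi = fit_cox(X, time, event)
    return IndependenceResult(uni, multi, collinear)
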