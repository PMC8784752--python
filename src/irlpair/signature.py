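"""Pair-signature construction: Cox fits, Lasso path, stepwise AIC, ROC, cutoff.

Selection runs in three stages on the filtered pair-score matrix:

1. univariate Cox screen — one single-covariate proportional-hazards fit per
   pair, keeping Wald p < 0.05 (batch Newton-Raphson, vectorized over pairs);
2. L1-penalized Cox over a descending penalty path with k-fold
   cross-validated partial-likelihood deviance choosing the penalty;
3. bidirectional stepwise multivariate Cox minimizing AIC, starting from
   the full Lasso-selected model.

The risk score of a sample is the coefficient-weighted sum of its binary
pair scores. Patients are dichotomized at the 3-year time-dependent ROC
cut value maximizing Youden's J (high risk iff score >= cutoff).

All Cox fits use the Breslow approximation for tied event times and
Newton-Raphson iterated to an infinity-norm gradient below 1e-8; monotone
partial likelihoods (perfect separation) are flagged, never raised.
The time-dependent ROC uses the cumulative-case / dynamic-control
Kaplan-Meier estimator (the classic survival-ROC construction), which
reduces exactly to the empirical ROC — and its AUC to the Mann-Whitney
statistic — when no subject is censored before the horizon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import ClinicalTable, DataError
from .pairs import PairScoreMatrix

logger = logging.getLogger("irlpair")

GRAD_TOL = 1e-8
MAX_ITER = 60
#: |beta| beyond this is treated as a monotone likelihood (separation): the
#: gradient decays like exp(-|beta|) there and can pass the tolerance while
#: the true maximizer is at infinity
BETA_BOUND = 15.0


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery
# ---------------------------------------------------------------------------

def _sorted_desc(time: np.ndarray, event: np.ndarray):
    """Sort descending by time; return order, sorted arrays and tie-block ends.

    With descending times, the risk set of an event at position i is the
    prefix 0..ends[i], where ends[i] is the last index of i's tie block.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="mergesort")
    t = time[order]
    ends = np.searchsorted(-t, -t, side="right") - 1
    return order, t, event[order], ends


def breslow_loglik_from_eta(eta, time, event) -> float:
    """Breslow log partial likelihood for a fixed linear predictor."""
    order, _, e, ends = _sorted_desc(time, event)
    lp = np.asarray(eta, dtype=float)[order]
    # saturated predictors may overflow exp(); the resulting -inf loglik
    # (infinite deviance) is the correct verdict for such a fit
    with np.errstate(over="ignore"):
        s0 = np.cumsum(np.exp(lp))[ends]
    ev = e == 1
    if not ev.any():
        raise DataError("partial likelihood requires at least one event")
    return float(lp[ev].sum() - np.log(s0[ev]).sum())


def _breslow_derivs(beta, X, e, ends):
    """(loglik, gradient, hessian) at beta on presorted (descending) data.

    The S2/S0 Hessian term is folded into a single GEMM: with prefix risk
    sets, sum_events S2(i)/S0(i) = X' diag(c * w) X where c_j is the suffix
    sum over event tie blocks (with end >= j) of (block event count)/S0.
    """
    lp = X @ beta
    w = np.exp(lp)
    cw = np.cumsum(w)
    s0 = cw[ends]
    cwx = np.cumsum(w[:, None] * X, axis=0)
    s1 = cwx[ends]
    ev = e == 1
    xbar = s1[ev] / s0[ev, None]
    ll = lp[ev].sum() - np.log(s0[ev]).sum()
    grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
    q = np.zeros(len(w))
    np.add.at(q, ends[ev], 1.0 / s0[ev])
    c = np.cumsum(q[::-1])[::-1]
    hess = -(X.T @ (X * (c * w)[:, None])) + np.einsum("ij,ik->jk", xbar, xbar)
    return float(ll), grad, hess


@dataclass
class CoxFitResult:
    """Multivariate Cox proportional-hazards fit summary."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    message: str = ""

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return lo, hi

    @property
    def p(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(self.beta) / self.se
        return 2.0 * stats.norm.sf(z)

    @property
    def aic(self) -> float:
        return 2.0 * len(self.beta) - 2.0 * self.loglik

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame({
            "beta": self.beta, "hr": self.hr,
            "ci_low": lo, "ci_high": hi,
            "se": self.se, "p": self.p,
        }, index=pd.Index(self.names, name="covariate"))


def fit_cox(X, time, event, names=None, max_iter=MAX_ITER, tol=GRAD_TOL,
            beta0=None) -> CoxFitResult:
    """Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    ``X`` is samples x k (DataFrame or array). Monotone likelihoods are
    returned flagged (``converged=False``) rather than raised; a constant
    covariate column is an error naming the column. ``beta0`` warm-starts
    the Newton iteration (default zero).
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise DataError("X must be samples x k")
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) != n or len(event) != n:
        raise DataError("time/event length mismatch with X")
    if event.sum() < 1:
        raise DataError("Cox fit requires at least one event")
    spans = np.ptp(X, axis=0)
    if (spans == 0).any():
        raise DataError(f"constant covariate column: {names[int(np.argmax(spans == 0))]!r}")

    order, _, e, ends = _sorted_desc(time, event)
    Xs = X[order]

    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess = _breslow_derivs(beta, Xs, e, ends)
    converged = False
    message = ""
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix (collinear or separated covariates)"
            break
        # damped Newton: halve until the partial likelihood does not decrease
        new_beta = beta + step
        ll_new, g_new, h_new = _breslow_derivs(new_beta, Xs, e, ends)
        halves = 0
        while ll_new < ll - 1e-12 and halves < 25:
            step *= 0.5
            new_beta = beta + step
            ll_new, g_new, h_new = _breslow_derivs(new_beta, Xs, e, ends)
            halves += 1
        beta, ll, grad, hess = new_beta, ll_new, g_new, h_new
        if np.max(np.abs(beta)) > BETA_BOUND:
            message = "monotone partial likelihood (separation suspected)"
            break
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
        else:
            message = "Newton-Raphson did not converge"
    if converged and np.max(np.abs(beta)) > BETA_BOUND:
        converged = False
        message = "monotone partial likelihood (separation suspected)"

    se = np.full(k, np.nan)
    if converged:
        try:
            se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        except np.linalg.LinAlgError:
            converged = False
            message = "singular information matrix at optimum"
    return CoxFitResult(list(names), beta, se, ll, int(event.sum()),
                        converged, message)


def loglik_null(time, event) -> float:
    """Breslow partial log likelihood of the empty (no-covariate) model."""
    return breslow_loglik_from_eta(np.zeros(len(np.asarray(time))), time, event)


# ---------------------------------------------------------------------------
# univariate screen (vectorized over binary pair covariates)
# ---------------------------------------------------------------------------

def _univariate_batch(Z: np.ndarray, time, event,
                      max_iter=MAX_ITER, tol=GRAD_TOL):
    """Single-covariate Breslow Cox fits for every row of binary matrix Z.

    Exploits z in {0,1}: exp(beta*z) = 1 + z*(e^beta - 1), so the score and
    information reduce to cumulative sums shared across pairs. Returns
    (beta, se, p, loglik, converged) arrays.
    """
    order, _, e, ends = _sorted_desc(time, event)
    Zs = np.asarray(Z, dtype=float)[:, order]
    ev = e == 1
    colsel = ends[ev]
    zsum_e = Zs[:, ev].sum(axis=1)

    P = Zs.shape[0]
    beta = np.zeros(P)
    g = np.zeros(P)
    h = np.ones(P)
    for _ in range(max_iter):
        u = np.exp(beta)
        w = 1.0 + Zs * (u - 1.0)[:, None]
        s0 = np.cumsum(w, axis=1)[:, colsel]
        s1 = np.cumsum(u[:, None] * Zs, axis=1)[:, colsel]
        a = s1 / s0
        g = zsum_e - a.sum(axis=1)
        h = (a - a * a).sum(axis=1)  # observed information (positive)
        active = (np.abs(g) >= tol) & (h > 0) & (np.abs(beta) <= BETA_BOUND)
        if not active.any():
            break
        step = np.zeros(P)
        step[active] = g[active] / h[active]
        np.clip(step, -1.0, 1.0, out=step)
        beta = beta + step
    u = np.exp(beta)
    w = 1.0 + Zs * (u - 1.0)[:, None]
    s0 = np.cumsum(w, axis=1)[:, colsel]
    ll = beta * zsum_e - np.log(s0).sum(axis=1)
    converged = (np.abs(g) < tol) & (np.abs(beta) <= BETA_BOUND) & (h > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(h > 0, np.sqrt(1.0 / h), np.nan)
        z = np.abs(beta) / se
    p = 2.0 * stats.norm.sf(z)
    return beta, se, p, ll, converged


def univariate_cox_screen(
    pm: PairScoreMatrix, clin: ClinicalTable, p_thresh: float = 0.05,
    chunk: int = 4000,
) -> tuple[list[str], pd.DataFrame]:
    """Single-pair Cox fits; retain Wald p < p_thresh.

    Separation-flagged pairs are excluded with a logged count. Returns
    (retained pair labels, per-pair results table).
    """
    if set(pm.sample_ids) != set(clin.sample_ids):
        raise DataError("pair matrix and clinical table cover different samples")
    clin = clin.subset(pm.sample_ids)
    time, event = clin.time, clin.event
    if event.sum() < 1:
        raise DataError("univariate screen requires at least one event")
    Z = pm.scores.to_numpy()
    parts = []
    for start in range(0, Z.shape[0], chunk):
        parts.append(_univariate_batch(Z[start:start + chunk], time, event))
    beta, se, p, ll, conv = (np.concatenate(xs) for xs in zip(*parts))
    table = pd.DataFrame({
        "beta": beta, "hr": np.exp(beta), "se": se, "p": p,
        "loglik": ll, "converged": conv,
    }, index=pm.scores.index)
    n_sep = int((~conv).sum())
    if n_sep:
        logger.warning("univariate screen excluded %d non-convergent pairs", n_sep)
    retained = list(table.index[(table["p"] < p_thresh) & table["converged"]])
    logger.info("univariate screen retained %d of %d pairs",
                len(retained), pm.n_pairs)
    return retained, table


# ---------------------------------------------------------------------------
# L1-penalized Cox with cross-validated deviance
# ---------------------------------------------------------------------------

@dataclass
class LassoCVResult:
    selected: list[str]
    best_alpha: float
    alphas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    rule: str
    seed: int | None


def lasso_cox_cv(
    pm: PairScoreMatrix,
    clin: ClinicalTable,
    folds: int = 10,
    seed: int | None = 0,
    rule: str = "min",
    alpha: float | None = None,
    n_alphas: int = 50,
) -> LassoCVResult:
    """L1-penalized Cox over a descending penalty path.

    The penalty is chosen to minimize the mean cross-validated Breslow
    partial-likelihood deviance (fold assignment seeded); ``rule="1se"``
    instead takes the largest penalty within one standard error of the
    minimum. Passing ``alpha`` skips cross-validation and selects at that
    fixed penalty. Returns the pairs with nonzero coefficient.
    """
    if pm.n_pairs < 2:
        raise DataError("Lasso needs at least 2 candidate pairs")
    clin = clin.subset(pm.sample_ids)
    time, event = clin.time, clin.event
    X = pm.scores.T.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    full = None
    for min_ratio in ("auto", 0.05, 0.2):
        try:
            full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                          alpha_min_ratio=min_ratio)
            full.fit(X, y)
            break
        except ArithmeticError:
            # glmnet overflow at tiny penalties (near-separation); shorten path
            full = None
    if full is None:
        raise DataError("penalized Cox path failed to converge numerically")
    path = np.asarray(full.alphas_)

    if alpha is not None:
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha])
        model.fit(X, y)
        sel = np.flatnonzero(np.abs(model.coef_[:, 0]) > 0)
        return LassoCVResult([pm.scores.index[i] for i in sel], float(alpha),
                             path, np.full_like(path, np.nan),
                             np.full_like(path, np.nan), "fixed", seed)

    if event.sum() < folds:
        raise DataError(
            f"{int(event.sum())} events < {folds} folds; use fewer folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.full((folds, len(path)), np.nan)
    for f, (tr, te) in enumerate(kf.split(X)):
        if event[te].sum() < 1 or event[tr].sum() < 1:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(path))
        try:
            m.fit(X[tr], Surv.from_arrays(event=event[tr].astype(bool),
                                          time=time[tr]))
        except ArithmeticError:
            logger.warning("Lasso CV fold %d failed numerically; skipped", f)
            continue
        got = {round(float(a), 12): j for j, a in enumerate(m.alphas_)}
        for i, a in enumerate(path):
            j = got.get(round(float(a), 12))
            if j is None:
                continue
            eta = X[te] @ m.coef_[:, j]
            dev[f, i] = -2.0 * breslow_loglik_from_eta(eta, time[te], event[te])
    mean_dev = np.nanmean(dev, axis=0)
    with np.errstate(invalid="ignore"):
        se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(dev), axis=0))
    best = int(np.nanargmin(mean_dev))
    if rule == "1se":
        bound = mean_dev[best] + se_dev[best]
        ok = np.flatnonzero(mean_dev <= bound)
        best = int(ok[0])  # path is descending: first index = largest alpha
    elif rule != "min":
        raise DataError(f"unknown CV rule {rule!r}")
    sel = np.flatnonzero(np.abs(full.coef_[:, best]) > 0)
    selected = [pm.scores.index[i] for i in sel]
    logger.info("Lasso CV selected %d pairs at alpha=%.5g",
                len(selected), path[best])
    return LassoCVResult(selected, float(path[best]), path, mean_dev,
                         se_dev, rule, seed)


# ---------------------------------------------------------------------------
# stepwise multivariate Cox (AIC)
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Final pair signature: ordered pairs with Cox coefficients."""

    pairs: list[str]
    betas: np.ndarray
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.betas):
            raise DataError("pairs/betas length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise DataError("duplicate pairs in signature")
        self.betas = np.asarray(self.betas, dtype=float)

    def save(self, path) -> None:
        doc = {
            "pairs": self.pairs,
            "betas": [float(b) for b in self.betas],
            "cutoff": self.cutoff,
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SignatureModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(doc["pairs"], np.asarray(doc["betas"]), doc.get("cutoff"),
                   doc.get("metadata", {}))


def stepwise_multivariate_cox(
    pm: PairScoreMatrix,
    clin: ClinicalTable,
    candidates: list[str] | None = None,
    max_steps: int = 200,
) -> SignatureModel:
    """Bidirectional stepwise Cox minimizing AIC, from the full model.

    At each step every single-pair drop and add is scored by AIC; the best
    strictly improving move is taken. A non-convergent full model falls back
    to forward-only search from the empty model (logged). Coefficients are
    re-fit at the final subset.
    """
    if candidates is None:
        candidates = list(pm.scores.index)
    if not candidates:
        raise DataError("stepwise search needs at least one candidate pair")
    clin = clin.subset(pm.sample_ids)
    time, event = clin.time, clin.event
    Z = pm.scores.loc[candidates]
    ll0 = loglik_null(time, event)

    cache: dict[frozenset, CoxFitResult | None] = {}
    warm: dict[str, float] = {}

    def fitted(subset: frozenset) -> CoxFitResult | None:
        if subset not in cache:
            if not subset:
                cache[subset] = None
            else:
                cols = [c for c in candidates if c in subset]
                beta0 = np.array([warm.get(c, 0.0) for c in cols])
                try:
                    res = fit_cox(Z.loc[cols].T, time, event, names=cols,
                                  beta0=beta0)
                except DataError:
                    res = None
                cache[subset] = res if res is not None and res.converged else None
        return cache[subset]

    def aic_of(subset: frozenset) -> float:
        if not subset:
            return -2.0 * ll0
        res = fitted(subset)
        return res.aic if res is not None else np.inf

    current = frozenset(candidates)
    forward_only = False
    if fitted(current) is None:
        logger.warning("full model non-convergent; forward-only stepwise from empty")
        current = frozenset()
        forward_only = True
    best_aic = aic_of(current)
    aic_path = [best_aic]

    for _ in range(max_steps):
        moves: list[frozenset] = [current | {c} for c in candidates
                                  if c not in current]
        if not forward_only:
            moves += [current - {c} for c in current]
        best_move, best_move_aic = None, best_aic
        for m in moves:
            a = aic_of(m)
            if a < best_move_aic - 1e-10:
                best_move, best_move_aic = m, a
        if best_move is None:
            break
        current, best_aic = best_move, best_move_aic
        aic_path.append(best_aic)
        res = fitted(current)
        if res is not None:
            warm = dict(zip(res.names, res.beta))

    if not current:
        return SignatureModel([], np.zeros(0), metadata={
            "aic": best_aic, "loglik": ll0, "aic_path": aic_path,
        })
    final = fitted(current)
    order = [c for c in candidates if c in current]
    return SignatureModel(order, final.beta.copy(), metadata={
        "aic": final.aic,
        "loglik": final.loglik,
        "aic_path": aic_path,
        "n_events": final.n_events,
        "se": [float(s) for s in final.se],
        "p": [float(x) for x in final.p],
    })


# ---------------------------------------------------------------------------
# risk scores, time-dependent ROC, cutoff
# ---------------------------------------------------------------------------

@dataclass
class RiskProfile:
    """Per-sample risk score with optional high/low dichotomization."""

    table: pd.DataFrame  # index sample_id; columns risk_score [, group]
    cutoff: float | None = None

    @property
    def risk(self) -> pd.Series:
        return self.table["risk_score"]

    @property
    def group(self) -> pd.Series:
        if "group" not in self.table.columns:
            raise DataError("risk profile has not been dichotomized")
        return self.table["group"]


def compute_risk_scores(model: SignatureModel, pm: PairScoreMatrix) -> RiskProfile:
    """Risk = sum_j beta_j * pair_score_j per sample."""
    missing = [p for p in model.pairs if p not in pm.scores.index]
    if missing:
        raise DataError(f"pair {missing[0]!r} absent from the score matrix")
    if model.pairs:
        S = pm.scores.loc[model.pairs].to_numpy(dtype=float)
        risk = model.betas @ S
    else:
        risk = np.zeros(len(pm.sample_ids))
    tab = pd.DataFrame({"risk_score": risk},
                       index=pd.Index(pm.sample_ids, name="sample_id"))
    return RiskProfile(tab)


def _km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit estimate S(t)."""
    order = np.argsort(time, kind="mergesort")
    ts, es = time[order], event[order]
    ev_times, d = np.unique(ts[(es == 1) & (ts <= t)], return_counts=True)
    if ev_times.size == 0:
        return 1.0
    n_risk = len(ts) - np.searchsorted(ts, ev_times, side="left")
    return float(np.prod(1.0 - d / n_risk))


@dataclass
class TimeDependentROC:
    horizon: float
    cut_values: np.ndarray  # ascending candidate cutoffs (observed risks)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    defined: bool = True


def td_roc(risk, time, event, horizon_days: float) -> TimeDependentROC:
    """Cumulative-case/dynamic-control ROC at a horizon, KM-weighted.

    Cases are subjects with an event by the horizon, controls are survivors
    past it; censoring before the horizon is handled by Kaplan-Meier
    estimates of the survival function overall and within each
    ``risk >= cut`` stratum. AUC by the trapezoid rule over the curve.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(risk).all():
        raise DataError("risk scores must be finite")
    s_all = _km_survival_at(time, event, horizon_days)
    if not (0.0 < s_all < 1.0):
        # no estimated cases or no estimated controls at the horizon
        cuts = np.unique(risk)
        nan = np.full(cuts.shape, np.nan)
        return TimeDependentROC(horizon_days, cuts, nan, nan, np.nan, False)
    cuts = np.unique(risk)  # ascending
    tpr = np.empty(cuts.shape)
    fpr = np.empty(cuts.shape)
    for i, c in enumerate(cuts):
        mask = risk >= c
        p_high = mask.mean()
        s_c = _km_survival_at(time[mask], event[mask], horizon_days)
        tpr[i] = np.clip((1.0 - s_c) * p_high / (1.0 - s_all), 0.0, 1.0)
        fpr[i] = np.clip(s_c * p_high / s_all, 0.0, 1.0)
    # walk the curve in descending-cut order from the (0,0) anchor; the
    # lowest cut already yields (1,1)
    fx = np.concatenate([[0.0], fpr[::-1]])
    ty = np.concatenate([[0.0], tpr[::-1]])
    auc = float(np.trapezoid(ty, fx))
    return TimeDependentROC(horizon_days, cuts, tpr, fpr, auc, True)


def select_cutoff(roc: TimeDependentROC) -> float:
    """Cut value maximizing Youden's J = tpr - fpr; ties go to the smallest cut."""
    if not roc.defined or roc.cut_values.size == 0:
        raise DataError("cannot select a cutoff on a degenerate ROC")
    j = roc.tpr - roc.fpr
    return float(roc.cut_values[int(np.argmax(j))])


def dichotomize(profile: RiskProfile, cutoff: float) -> RiskProfile:
    """Label samples high iff risk_score >= cutoff."""
    if not np.isfinite(cutoff):
        raise DataError("cutoff must be finite")
    tab = profile.table.copy()
    tab["group"] = np.where(tab["risk_score"] >= cutoff, "high", "low")
    return RiskProfile(tab, float(cutoff))


def write_risk_profile(profile: RiskProfile, path) -> None:
    out = profile.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_risk_profile(path) -> RiskProfile:
    tab = pd.read_csv(path, sep="\t", index_col="sample_id")
    return RiskProfile(tab)
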