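import numpy as np
import pandas as pd
import pytest

import irlpair as il
from irlpair.io import ClinicalTable, DataError
from irlpair.pairs import PairScoreMatrix
from irlpair.signature import (
    _univariate_batch,
    breslow_loglik_from_eta,
    loglik_null,
)

from oracles import grid_cox_beta, mann_whitney_auc, naive_breslow_loglik


def _clin(time, event):
    return ClinicalTable(pd.DataFrame(
        {"time_days": np.asarray(time, float), "event": np.asarray(event, int)},
        index=[f"S{i}" for i in range(len(time))]))


def _pm(rows, samples=None, labels=None):
    rows = np.asarray(rows, dtype=np.int8)
    labels = labels or [f"A{i:02d}|B{i:02d}" for i in range(rows.shape[0])]
    samples = samples or [f"S{j}" for j in range(rows.shape[1])]
    return PairScoreMatrix(pd.DataFrame(rows, index=labels, columns=samples))


class TestFitCox:
    def test_closed_form_toy(self):
        """Binary covariate, deaths x=1 at {1,4} and x=0 at {2,3}: the score
        equation 2u^2 + 2u - 2 = 0 gives beta = ln((sqrt(5)-1)/2)."""
        X = np.array([[1.0], [0.0], [0.0], [1.0]])
        res = il.fit_cox(X, [1, 2, 3, 4], [1, 1, 1, 1])
        assert res.converged
        assert res.beta[0] == pytest.approx(np.log((np.sqrt(5) - 1) / 2),
                                            abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            n = int(rng.integers(8, 30))
            x = rng.normal(size=(n, 1))
            t = rng.exponential(10 * np.exp(-0.5 * x[:, 0]))
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() < 2:
                continue
            res = il.fit_cox(x, t, e)
            if not res.converged:
                continue
            assert abs(res.beta[0] - grid_cox_beta(x[:, 0], t, e)) < 1e-4

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        n = 60
        X = rng.normal(size=(n, 3))
        t = rng.exponential(10 * np.exp(-X @ [0.5, -0.3, 0.0]))
        e = (rng.random(n) < 0.8).astype(int)
        res = il.fit_cox(X, t, e, names=["a", "b", "c"])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")  # no tied times: Efron == Breslow
        np.testing.assert_allclose(res.beta, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.se, cph.standard_errors_.to_numpy(),
                                   atol=1e-4)

    def test_constant_column_named(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DataError, match="x0"):
            il.fit_cox(X, np.arange(1.0, 6), np.ones(5, int))

    def test_separation_flagged_not_raised(self):
        # all x=1 events strictly precede all x=0 events
        X = np.array([[1.0]] * 4 + [[0.0]] * 4)
        t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        res = il.fit_cox(X, t, np.ones(8, int))
        assert not res.converged
        assert "separation" in res.message or "converge" in res.message

    def test_loglik_matches_naive_oracle(self, rng):
        n = 25
        eta = rng.normal(size=n)
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.7).astype(int)
        assert breslow_loglik_from_eta(eta, t, e) == pytest.approx(
            naive_breslow_loglik(eta, t, e), abs=1e-10)

    def test_aic_null_consistency(self, rng):
        t = rng.exponential(5, 20)
        e = np.ones(20, int)
        assert loglik_null(t, e) == pytest.approx(
            naive_breslow_loglik(np.zeros(20), t, e), abs=1e-10)


class TestUnivariateScreen:
    def test_batch_agrees_with_general_fit(self, rng):
        Z = (rng.random((15, 80)) < 0.5).astype(np.int8)
        t = rng.exponential(100, 80)
        e = (rng.random(80) < 0.6).astype(int)
        beta, se, p, ll, conv = _univariate_batch(Z, t, e)
        for i in range(0, 15, 3):
            ref = il.fit_cox(Z[i][:, None].astype(float), t, e)
            assert conv[i] == ref.converged
            if ref.converged:
                assert beta[i] == pytest.approx(ref.beta[0], abs=1e-7)
                assert p[i] == pytest.approx(ref.p[0], abs=1e-7)

    def test_separated_pair_excluded(self, rng):
        # pair 0 perfectly tracks the event order -> monotone likelihood
        n = 20
        t = np.arange(1.0, n + 1)
        e = np.ones(n, int)
        z_sep = (t <= 10).astype(np.int8)
        z_ok = (rng.random(n) < 0.5).astype(np.int8)
        pm = _pm([z_sep, z_ok])
        retained, table = il.univariate_cox_screen(pm, _clin(t, e))
        assert not table["converged"].iloc[0]
        assert table.index[0] not in retained


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(10)
    n, p_noise = 250, 40
    z_true = (rng.random((3, n)) < 0.5).astype(np.int8)
    z_noise = (rng.random((p_noise, n)) < 0.5).astype(np.int8)
    lp = np.array([1.0, 0.9, 0.8]) @ z_true
    t = rng.exponential(1000 * np.exp(-lp))
    c = rng.uniform(0, 2000, n)
    time = np.maximum(np.minimum(t, c), 1.0)
    event = (t <= c).astype(int)
    rows = np.vstack([z_true, z_noise])
    labels = [f"T{i:02d}|U{i:02d}" for i in range(3)] + \
             [f"N{i:02d}|M{i:02d}" for i in range(p_noise)]
    return _pm(rows, labels=labels), _clin(time, event), labels[:3]


class TestLassoCoxCV:

    def test_recovers_planted_and_deterministic(self, planted):
        pm, clin, truth = planted
        r1 = il.lasso_cox_cv(pm, clin, folds=10, seed=3)
        r2 = il.lasso_cox_cv(pm, clin, folds=10, seed=3)
        assert r1.selected == r2.selected
        assert set(truth) <= set(r1.selected)

    def test_path_maximum_selects_nothing(self, planted):
        pm, clin, _ = planted
        probe = il.lasso_cox_cv(pm, clin, folds=5, seed=0)
        res = il.lasso_cox_cv(pm, clin, alpha=float(probe.alphas[0]) * 10)
        assert res.selected == []

    def test_too_few_events_error(self):
        rng = np.random.default_rng(1)
        pm = _pm((rng.random((5, 12)) < 0.5).astype(int))
        clin = _clin(rng.exponential(10, 12),
                     [1, 1, 1] + [0] * 9)
        with pytest.raises(DataError, match="folds"):
            il.lasso_cox_cv(pm, clin, folds=10, seed=0)


class TestStepwise:
    def _survival(self, z, beta, rng, scale=1000.0):
        lp = beta * z
        t = rng.exponential(scale * np.exp(-lp))
        c = rng.uniform(0, 2 * scale, len(z))
        return np.maximum(np.minimum(t, c), 1.0), (t <= c).astype(int)

    def test_keeps_informative_drops_noise(self):
        rng = np.random.default_rng(21)
        n = 400
        z_info = (rng.random(n) < 0.5).astype(np.int8)
        z_noise = (rng.random(n) < 0.5).astype(np.int8)
        time, event = self._survival(z_info, 1.0, rng)
        pm = _pm([z_info, z_noise], labels=["A|B", "C|D"])
        model = il.stepwise_multivariate_cox(pm, _clin(time, event))
        assert "A|B" in model.pairs
        assert model.metadata["aic"] <= model.metadata["aic_path"][0]

    def test_single_covariate_degenerates_to_aic_comparison(self):
        rng = np.random.default_rng(4)
        z = (rng.random(200) < 0.5).astype(np.int8)
        time, event = self._survival(z, 1.0, rng)
        pm = _pm([z], labels=["A|B"])
        model = il.stepwise_multivariate_cox(pm, _clin(time, event))
        clin = _clin(time, event)
        full = il.fit_cox(z[:, None].astype(float), time, event)
        # informative covariate: AIC(model) < AIC(empty)
        assert model.pairs == ["A|B"]
        assert full.aic < -2 * loglik_null(time, event)

    def test_duplicated_covariate_never_kept_twice(self):
        rng = np.random.default_rng(8)
        z = (rng.random(300) < 0.5).astype(np.int8)
        time, event = self._survival(z, 1.0, rng)
        pm = _pm([z, z.copy()], labels=["A|B", "A2|B2"])
        model = il.stepwise_multivariate_cox(pm, _clin(time, event))
        assert len(model.pairs) == 1

    def test_aic_path_monotone(self, small_pipeline):
        path = small_pipeline.model.metadata["aic_path"]
        assert (np.diff(path) < 0).all()


class TestRiskScores:
    def test_arithmetic(self):
        pm = _pm(np.array([[1], [0], [1]]), samples=["S0"],
                 labels=["A|B", "C|D", "E|F"])
        model = il.SignatureModel(["A|B", "C|D", "E|F"],
                                  np.array([0.5, -1.0, 2.0]))
        prof = il.compute_risk_scores(model, pm)
        assert prof.risk.iloc[0] == pytest.approx(2.5)

    def test_zero_betas_zero_risk(self):
        pm = _pm(np.array([[1, 0], [0, 1]]), labels=["A|B", "C|D"])
        model = il.SignatureModel(["A|B", "C|D"], np.zeros(2))
        assert (il.compute_risk_scores(model, pm).risk == 0).all()

    def test_missing_pair_named(self):
        pm = _pm(np.array([[1, 0]]), labels=["A|B"])
        model = il.SignatureModel(["A|B", "X|Y"], np.array([1.0, 2.0]))
        with pytest.raises(DataError, match="X|Y"):
            il.compute_risk_scores(model, pm)

    def test_orientation_flip_shifts_risk_by_constant(self, rng):
        rows = (rng.random((4, 30)) < 0.5).astype(np.int8)
        labels = ["A|B", "C|D", "E|F", "G|H"]
        betas = rng.normal(size=4)
        pm = _pm(rows, labels=labels)
        r1 = il.compute_risk_scores(il.SignatureModel(labels, betas), pm).risk
        flipped = rows.copy()
        flipped[2] = 1 - flipped[2]  # mirror pair E|F, negate its beta
        b2 = betas.copy()
        b2[2] = -b2[2]
        pm2 = _pm(flipped, labels=labels)
        r2 = il.compute_risk_scores(il.SignatureModel(labels, b2), pm2).risk
        diff = (r2 - r1).to_numpy()
        np.testing.assert_allclose(diff, diff[0], atol=1e-12)
        assert (np.argsort(r1.to_numpy(), kind="stable")
                == np.argsort(r2.to_numpy(), kind="stable")).all()


class TestTimeDependentROC:
    def test_perfect_separation(self):
        roc = il.td_roc([0.1, 0.2, 0.8, 0.9], [100.0, 200, 10, 20],
                        [0, 0, 1, 1], 50.0)
        assert roc.auc == pytest.approx(1.0)
        assert il.select_cutoff(roc) == pytest.approx(0.8)

    def test_equals_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            risk = rng.normal(size=n)
            t = rng.exponential(50, n)
            hor = float(np.median(t))
            roc = il.td_roc(risk, t, np.ones(n, int), hor)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(risk, t <= hor), abs=1e-10)

    def test_null_risk_auc_near_half(self):
        rng = np.random.default_rng(5)
        inside = 0
        for _ in range(10):
            n = 1000
            risk = rng.normal(size=n)
            t = rng.exponential(1500, n)
            c = rng.uniform(0, 3000, n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            roc = il.td_roc(risk, time, event, 1000.0)
            inside += 0.45 < roc.auc < 0.55
        assert inside >= 9

    def test_undefined_when_no_cases(self):
        roc = il.td_roc([0.1, 0.5], [500.0, 600.0], [0, 0], 100.0)
        assert not roc.defined and np.isnan(roc.auc)
        with pytest.raises(DataError):
            il.select_cutoff(roc)


class TestCutoffAndGroups:
    def test_flat_roc_returns_smallest_cut(self):
        roc = il.TimeDependentROC(100.0, np.array([1.0, 2.0, 3.0]),
                                  np.array([0.9, 0.5, 0.1]),
                                  np.array([0.9, 0.5, 0.1]), 0.5)
        assert il.select_cutoff(roc) == 1.0

    def test_unique_interior_maximum(self):
        roc = il.TimeDependentROC(100.0, np.array([1.0, 2.0, 3.0]),
                                  np.array([1.0, 0.9, 0.3]),
                                  np.array([0.9, 0.4, 0.2]), 0.7)
        assert il.select_cutoff(roc) == 2.0

    def test_dichotomize_boundary(self):
        prof = il.RiskProfile(pd.DataFrame(
            {"risk_score": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]))
        out = il.dichotomize(prof, 2.0)
        assert list(out.group) == ["low", "high", "high"]
        assert (il.dichotomize(prof, 0.0).group == "high").all()
        assert (il.dichotomize(prof, 99.0).group == "low").all()
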