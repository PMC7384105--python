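"""Multinomial logit, block tests, stage plans with frozen-offset updating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from lcpa.prediction import (
    Stage,
    StagePlan,
    default_stage_plan,
    fit_multinomial,
    lr_block_test,
    run_stage_plan,
    update_with_wave,
    wald_block_test,
)

# fixed 12-row toy: 3 classes, one continuous predictor, classes overlap in x
TOY_X = np.array([0.2, -1.1, 0.5, 1.8, -0.4, 0.9, 2.1, -2.0, 0.0, 1.2, -0.7, 1.5])
TOY_Y = np.array([0, 1, 2, 0, 2, 1, 1, 0, 2, 0, 1, 2])


def _oracle_mnl(X, y, K):
    """Independent brute-force maximizer of the multinomial likelihood."""
    n, P = X.shape

    def negll(b):
        B = b.reshape(P, K - 1)
        eta = np.concatenate([np.zeros((n, 1)), X @ B], axis=1)
        lse = np.log(np.exp(eta - eta.max(1, keepdims=True)).sum(1)) + eta.max(1)
        return -(eta[np.arange(n), y] - lse).sum()

    best = None
    for s in range(4):
        rng = np.random.default_rng(s)
        res = minimize(negll, rng.normal(scale=0.5, size=P * (K - 1)),
                       method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        res = minimize(negll, res.x, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x.reshape(P, K - 1), -best.fun


class TestFitMultinomial:
    def test_intercept_only_probabilities_equal_proportions(self):
        X = np.ones((len(TOY_Y), 1))
        model = fit_multinomial(X, TOY_Y, 3)
        props = np.array([(TOY_Y == k).mean() for k in range(3)])
        np.testing.assert_allclose(model.prob, np.tile(props, (len(TOY_Y), 1)),
                                   atol=1e-12)

    def test_newton_matches_bruteforce_oracle(self):
        X = np.column_stack([np.ones(len(TOY_X)), TOY_X])
        model = fit_multinomial(X, TOY_Y, 3)
        B_oracle, ll_oracle = _oracle_mnl(X, TOY_Y, 3)
        np.testing.assert_allclose(model.coef, B_oracle, atol=1e-4)
        assert model.loglik == pytest.approx(ll_oracle, abs=1e-6)

    def test_matches_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        X = np.column_stack([np.ones(len(TOY_X)), TOY_X])
        ref = sm.MNLogit(TOY_Y, X).fit(disp=0, method="newton", tol=1e-12)
        model = fit_multinomial(X, TOY_Y, 3)
        np.testing.assert_allclose(model.coef, ref.params, atol=1e-6)

    def test_probability_rows_sum_to_one(self):
        X = np.column_stack([np.ones(len(TOY_X)), TOY_X])
        model = fit_multinomial(X, TOY_Y, 3)
        np.testing.assert_allclose(model.prob.sum(axis=1), 1.0, atol=1e-12)

    def test_adding_noise_predictor_never_hurts_loglik(self):
        rng = np.random.default_rng(5)
        X1 = np.column_stack([np.ones(len(TOY_X)), TOY_X])
        X2 = np.column_stack([X1, rng.normal(size=len(TOY_X))])
        m1 = fit_multinomial(X1, TOY_Y, 3)
        m2 = fit_multinomial(X2, TOY_Y, 3)
        assert m2.loglik >= m1.loglik - 1e-10

    def test_separation_triggers_ridge_with_warning(self):
        X = np.column_stack([np.ones(6), np.array([-3.0, -2, -1, 1, 2, 3])])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            model = fit_multinomial(X, y, 2)
        assert model.ridge > 0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_multinomial(np.ones((4, 1)), np.zeros(4, dtype=int), 2)


class TestBlockTests:
    def test_wald_df_bookkeeping(self):
        rng = np.random.default_rng(6)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.integers(0, 4, size=n)
        model = fit_multinomial(X, y, 4, colnames=["intercept", "a", "b", "c"])
        _, df1, _ = wald_block_test(model, ["a"])
        _, df2, _ = wald_block_test(model, ["a", "b"])
        assert df1 == 3 and df2 == 6

    def test_wald_null_statistic_calibrated(self):
        # under a null block, the statistic should average about its df
        rng = np.random.default_rng(7)
        stats_ = []
        for _ in range(40):
            n = 250
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.integers(0, 3, size=n)
            model = fit_multinomial(X, y, 3, colnames=["intercept", "a", "b"])
            s, df, _ = wald_block_test(model, ["a", "b"])
            stats_.append(s)
        assert df == 4
        assert np.mean(stats_) == pytest.approx(df, rel=0.3)

    def test_lr_identical_models_zero(self):
        X = np.column_stack([np.ones(len(TOY_X)), TOY_X])
        m = fit_multinomial(X, TOY_Y, 3, colnames=["intercept", "x"])
        stat, df, p = lr_block_test(m, m)
        assert stat == 0.0
        assert df == 0
        assert p == 1.0

    def test_lr_df_and_wald_agreement_large_n(self):
        rng = np.random.default_rng(8)
        n = 2500
        X1 = np.column_stack([np.ones(n), rng.normal(size=n)])
        extra = rng.normal(size=(n, 2))
        eta = np.column_stack([
            0.4 * X1[:, 1] + 0.3 * extra[:, 0],
            -0.2 * X1[:, 1] + 0.25 * extra[:, 1],
        ])
        full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        p = np.exp(full) / np.exp(full).sum(1, keepdims=True)
        y = np.array([rng.choice(3, p=pi) for pi in p])
        X2 = np.column_stack([X1, extra])
        m1 = fit_multinomial(X1, y, 3, colnames=["intercept", "x"])
        m2 = fit_multinomial(X2, y, 3, colnames=["intercept", "x", "e1", "e2"])
        lr_stat, lr_df, _ = lr_block_test(m1, m2)
        w_stat, w_df, _ = wald_block_test(m2, ["e1", "e2"])
        assert lr_df == w_df == 4
        assert lr_stat == pytest.approx(w_stat, rel=0.2)

    def test_non_nested_inputs_error(self):
        rng = np.random.default_rng(11)
        X1 = np.column_stack([np.ones(len(TOY_X)), TOY_X])
        X2 = np.column_stack([np.ones(len(TOY_X)), rng.normal(size=len(TOY_X))])
        m1 = fit_multinomial(X1, TOY_Y, 3, colnames=["intercept", "x"])
        m2 = fit_multinomial(X2, TOY_Y, 3, colnames=["intercept", "other"])
        with pytest.raises(ValueError, match="nested"):
            lr_block_test(m1, m2)  # same size but different predictors
        with pytest.raises(ValueError):
            lr_block_test(m2, m1)


class TestOffsetUpdating:
    def _baseline(self, n=400, seed=9):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        eta = np.column_stack([0.8 * X[:, 1], -0.5 * X[:, 1]])
        full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        p = np.exp(full) / np.exp(full).sum(1, keepdims=True)
        y = np.array([rng.choice(3, p=pi) for pi in p])
        return X, y, rng

    def test_offsets_are_not_reestimated(self):
        X, y, rng = self._baseline()
        base = fit_multinomial(X, y, 3, colnames=["intercept", "x"])
        wave = rng.normal(size=(len(y), 1))
        upd = update_with_wave(base, X, wave, y, ["w"])
        assert upd.coef.shape == (2, 2)  # intercept + wave only
        assert upd.loglik >= base.loglik - 1e-8

    def test_duplicated_wave_variables_error_by_default(self):
        X, y, _ = self._baseline()
        base = fit_multinomial(X, y, 3, colnames=["intercept", "x"])
        with pytest.raises(ValueError, match="overlap"):
            update_with_wave(base, X, X[:, 1:], y, ["x"])

    def test_duplicated_wave_nests_baseline_when_allowed(self):
        X, y, _ = self._baseline()
        base = fit_multinomial(X, y, 3, colnames=["intercept", "x"])
        upd = update_with_wave(base, X, X[:, 1:], y, ["x"], allow_overlap=True)
        assert upd.loglik >= base.loglik - 1e-8
        # nothing left to absorb: new coefficients stay near zero
        assert np.abs(upd.coef[1]).max() < 0.2

    def test_zero_signal_wave_keeps_own_class_probabilities(self):
        X, y, rng = self._baseline(n=800)
        base = fit_multinomial(X, y, 3, colnames=["intercept", "x"])
        wave = rng.normal(size=(len(y), 2))
        upd = update_with_wave(base, X, wave, y, ["w1", "w2"])
        own_base = base.prob[np.arange(len(y)), y].mean()
        own_upd = upd.prob[np.arange(len(y)), y].mean()
        assert own_upd == pytest.approx(own_base, abs=0.03)


class TestStagePlan:
    def test_stage_plan_validates_baseline_references(self):
        with pytest.raises(ValueError):
            StagePlan([Stage("a", ["x"], use_baseline_offsets="missing")])

    def test_uninformative_predictors_track_chance(self):
        rng = np.random.default_rng(10)
        n = 600
        df = pd.DataFrame({"x": rng.normal(size=n)})
        labels = rng.choice(3, size=n, p=[0.5, 0.3, 0.2])
        plan = StagePlan([Stage("only", ["x"])])
        res = run_stage_plan(df, labels, plan, K=3)[0]
        np.testing.assert_allclose(
            res.summary["mean"].to_numpy(), res.chance, atol=0.05
        )

    def test_perfectly_separating_predictor_saturates(self):
        n = 90
        labels = np.repeat([0, 1, 2], n // 3)
        df = pd.DataFrame({"x": labels.astype(float)})
        plan = StagePlan([Stage("only", ["x"])])
        with pytest.warns(UserWarning):
            res = run_stage_plan(df, labels, plan, K=3)[0]
        assert res.summary["mean"].min() > 0.95

    def test_age_graded_signal_improves_prediction(self, gen_config):
        from lcpa.simulate import generate_cohort

        table, truth = generate_cohort(gen_config, n=600, seed=12)
        plan = default_stage_plan()
        res = run_stage_plan(
            table.data, truth, plan,
            include=table.include_predictive.to_numpy(), K=4, ridge=1e-4,
        )
        by_name = {r.stage.name: r for r in res}
        m2 = by_name["age2_css_iq"].summary["mean"].mean()
        m3 = by_name["age3_update"].summary["mean"].mean()
        m9 = by_name["age9_update"].summary["mean"].mean()
        assert m3 >= m2 - 1e-6
        assert m9 >= m3 - 1e-6
        assert m9 > m2 + 0.05

    def test_stage_loglik_nondecreasing_for_nested_stages(self, gen_config):
        from lcpa.simulate import generate_cohort

        table, truth = generate_cohort(gen_config, n=400, seed=13)
        plan = StagePlan([
            Stage("nonclinical", ["non_caucasian", "female", "maternal_edu", "site"]),
            Stage("css", ["css_2"]),
            Stage("iq", ["viq_2", "nviq_2"]),
        ])
        res = run_stage_plan(table.data, truth, plan,
                             include=table.include_predictive.to_numpy(), K=4)
        # same rows across these stages -> likelihood must be monotone
        assert len({tuple(r.rows) for r in res}) == 1
        lls = [r.model.loglik for r in res]
        assert np.all(np.diff(lls) >= -1e-8)
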