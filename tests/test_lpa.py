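"""Mixture engine: densities, EM steps, FIML, parameter counting, BIC."""

import numpy as np
import pytest
from scipy.special import expit, logsumexp
from scipy.stats import norm, poisson

from lcpa.lpa import (
    EmptyClassError,
    MixtureParams,
    bic,
    case_loglik,
    component_logdensity,
    count_parameters,
    e_step,
    enumerate_classes,
    fit_em,
    fit_ordinal_weighted,
    loglik,
    m_step,
)
from lcpa.variables import VariableSpec, default_indicator_specs


def toy_params_2class():
    """Two classes over one gaussian, one 3-level ordinal, one count."""
    p = MixtureParams(K=2, mixing=np.array([0.6, 0.4]))
    p.means["g"] = np.array([-1.0, 2.0])
    p.variances["g"] = 1.5
    p.cutpoints["o"] = np.array([-1.0, 1.0])
    p.locations["o"] = np.array([0.0, 1.2])
    p.log_rates["c"] = np.array([0.0, np.log(3.0)])
    return p


TOY_SPECS = [
    VariableSpec("g", "gaussian"),
    VariableSpec("o", "ordinal", n_levels=3),
    VariableSpec("c", "count"),
]


class TestComponentLogdensity:
    def test_ordinal_logistic_probabilities(self):
        # cutpoints (-1, 1), location 0: levels get (F(-1), F(1)-F(-1), 1-F(1))
        p = toy_params_2class()
        spec = TOY_SPECS[1]
        probs = [np.exp(component_logdensity(spec, p, 0, lev)) for lev in (1, 2, 3)]
        np.testing.assert_allclose(probs, [0.2689, 0.4621, 0.2689], atol=1e-4)
        assert sum(probs) == pytest.approx(1.0)

    def test_gaussian_closed_form(self):
        p = MixtureParams(K=1, mixing=np.array([1.0]))
        p.means["g"] = np.array([0.0])
        p.variances["g"] = 1.0
        got = component_logdensity(VariableSpec("g", "gaussian"), p, 0, 0.0)
        assert got == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)))

    def test_poisson_rate_one_at_zero(self):
        p = MixtureParams(K=1, mixing=np.array([1.0]))
        p.log_rates["c"] = np.array([0.0])
        got = component_logdensity(VariableSpec("c", "count"), p, 0, 0.0)
        assert got == pytest.approx(-1.0)

    @pytest.mark.parametrize("value", [0, 11, 2.5])
    def test_ordinal_out_of_support(self, value):
        p = toy_params_2class()
        spec = VariableSpec("o", "ordinal", n_levels=3)
        with pytest.raises(ValueError, match="o"):
            component_logdensity(spec, p, 0, value)

    def test_negative_count_rejected(self):
        p = toy_params_2class()
        with pytest.raises(ValueError, match="c"):
            component_logdensity(TOY_SPECS[2], p, 0, -1.0)


class TestCaseLoglik:
    def test_fully_missing_row_contributes_zero(self):
        p = toy_params_2class()
        row = np.array([np.nan, np.nan, np.nan])
        assert case_loglik(p, row, TOY_SPECS) == pytest.approx(0.0, abs=1e-14)

    def test_single_class_equals_component_density(self):
        p = MixtureParams(K=1, mixing=np.array([1.0]))
        p.means["g"] = np.array([0.5])
        p.variances["g"] = 2.0
        row = np.array([1.3])
        got = case_loglik(p, row, [VariableSpec("g", "gaussian")])
        assert got == pytest.approx(norm.logpdf(1.3, 0.5, np.sqrt(2.0)))

    def test_matches_bruteforce_class_enumeration(self):
        # independent oracle: explicit sum over classes with scipy densities
        p = toy_params_2class()
        row = np.array([0.7, 2.0, 4.0])
        per_class = []
        for k in range(2):
            lg = norm.logpdf(0.7, p.means["g"][k], np.sqrt(p.variances["g"]))
            F = expit(p.cutpoints["o"] - p.locations["o"][k])
            lo = np.log(F[1] - F[0])  # level 2
            lc = poisson.logpmf(4, np.exp(p.log_rates["c"][k]))
            per_class.append(np.log(p.mixing[k]) + lg + lo + lc)
        expected = logsumexp(per_class)
        assert case_loglik(p, row, TOY_SPECS) == pytest.approx(expected, abs=1e-12)

    def test_fiml_skips_missing_components(self):
        p = toy_params_2class()
        row = np.array([0.7, np.nan, np.nan])
        per_class = [
            np.log(p.mixing[k])
            + norm.logpdf(0.7, p.means["g"][k], np.sqrt(p.variances["g"]))
            for k in range(2)
        ]
        assert case_loglik(p, row, TOY_SPECS) == pytest.approx(
            logsumexp(per_class), abs=1e-12
        )


class TestESteps:
    def test_single_class_all_ones(self):
        p = MixtureParams(K=1, mixing=np.array([1.0]))
        p.means["g"] = np.array([0.0])
        p.variances["g"] = 1.0
        post, _ = e_step(p, np.array([[0.1], [2.0]]), [VariableSpec("g", "gaussian")])
        np.testing.assert_allclose(post, 1.0)

    def test_identical_classes_give_uniform_posterior(self):
        p = MixtureParams(K=2, mixing=np.array([0.5, 0.5]))
        p.means["g"] = np.array([1.0, 1.0])
        p.variances["g"] = 1.0
        post, _ = e_step(p, np.array([[0.0], [5.0]]), [VariableSpec("g", "gaussian")])
        np.testing.assert_allclose(post, 0.5)

    def test_bayes_rule_hand_computation(self):
        p = MixtureParams(K=2, mixing=np.array([0.3, 0.7]))
        p.means["g"] = np.array([0.0, 3.0])
        p.variances["g"] = 1.0
        spec = [VariableSpec("g", "gaussian")]
        rows = np.array([[0.0], [1.5], [3.0]])
        post, _ = e_step(p, rows, spec)
        for i, y in enumerate([0.0, 1.5, 3.0]):
            a = 0.3 * norm.pdf(y, 0, 1)
            b = 0.7 * norm.pdf(y, 3, 1)
            assert post[i, 0] == pytest.approx(a / (a + b), abs=1e-12)

    def test_fully_missing_rows_get_prior(self):
        p = toy_params_2class()
        post, _ = e_step(p, np.full((3, 3), np.nan), TOY_SPECS)
        np.testing.assert_allclose(post, np.tile(p.mixing, (3, 1)))

    def test_rows_normalized(self, fitted_500):
        np.testing.assert_allclose(
            fitted_500.posterior.sum(axis=1), 1.0, atol=1e-12
        )


class TestMStep:
    def test_degenerate_single_class_closed_forms(self):
        rng = np.random.default_rng(0)
        n = 200
        Y = np.column_stack([
            rng.normal(1.0, 2.0, n),
            rng.integers(1, 4, n).astype(float),
            rng.poisson(2.0, n).astype(float),
        ])
        post = np.ones((n, 1))
        p = m_step(post, Y, TOY_SPECS)
        assert p.means["g"][0] == pytest.approx(Y[:, 0].mean())
        assert p.variances["g"] == pytest.approx(Y[:, 0].var())  # MLE, ddof 0
        assert np.exp(p.log_rates["c"][0]) == pytest.approx(Y[:, 2].mean())

    def test_uniform_posteriors_give_identical_classes(self):
        rng = np.random.default_rng(1)
        n = 100
        Y = np.column_stack([
            rng.normal(size=n),
            rng.integers(1, 4, n).astype(float),
            rng.poisson(1.5, n).astype(float),
        ])
        post = np.full((n, 3), 1 / 3)
        p = m_step(post, Y, TOY_SPECS)
        assert np.ptp(p.means["g"]) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(p.log_rates["c"]) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(p.locations["o"]) == pytest.approx(0.0, abs=1e-6)

    def test_ordinal_inner_solve_beats_grid_oracle(self):
        # brute-force grid over (tau1, tau2, eta2) for K=2, L=3
        W = np.array([[30.0, 12.0, 4.0], [5.0, 14.0, 25.0]])

        def wll(tau, eta):
            a = tau[None, :] - np.array(eta)[:, None]
            F = expit(a)
            cum = np.concatenate([np.zeros((2, 1)), F, np.ones((2, 1))], axis=1)
            pr = np.clip(np.diff(cum, axis=1), 1e-12, 1)
            return (W * np.log(pr)).sum()

        best = -np.inf
        for t1 in np.linspace(-3, 1, 41):
            for dt in np.linspace(0.05, 4, 40):
                for e2 in np.linspace(-1, 4, 51):
                    v = wll(np.array([t1, t1 + dt]), [0.0, e2])
                    best = max(best, v)
        tau, eta = fit_ordinal_weighted(W, np.array([-0.5, 0.5]), np.zeros(2))
        assert wll(tau, eta) >= best - 1e-4

    def test_empty_class_flagged(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(50, 1))
        post = np.zeros((50, 2))
        post[:, 0] = 1.0
        with pytest.raises(EmptyClassError):
            m_step(post, Y, [VariableSpec("g", "gaussian")])


class TestFitEM:
    def test_single_class_closed_form_negloglik(self):
        rng = np.random.default_rng(3)
        y = rng.normal(2.0, 1.5, 300)
        spec = [VariableSpec("g", "gaussian")]
        fit = fit_em(y[:, None], spec, K=1, n_restarts=1, seed=0)
        mu, var = y.mean(), y.var()
        expected = -norm.logpdf(y, mu, np.sqrt(var)).sum()
        assert fit.neg_loglik == pytest.approx(expected, abs=1e-6)

    def test_monotone_loglik_trace(self, fitted_500):
        trace = np.array(fitted_500.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * (1 + np.abs(trace[:-1])))

    def test_label_permutation_invariance(self, processed_500, fitted_500):
        Y, specs, _ = processed_500
        perm = fitted_500.params.permute([2, 0, 3, 1])
        assert loglik(perm, Y, specs) == pytest.approx(
            -fitted_500.neg_loglik, abs=1e-6
        )

    def test_fiml_appending_missing_rows_is_invariant(self, processed_500, fitted_500):
        Y, specs, _ = processed_500
        Y_aug = np.vstack([Y, np.full((10, Y.shape[1]), np.nan)])
        # identical total log-likelihood under the same parameters
        assert loglik(fitted_500.params, Y_aug, specs) == pytest.approx(
            -fitted_500.neg_loglik, abs=1e-10
        )
        # refitting with the appended empty rows reproduces the estimates
        refit = fit_em(Y_aug, specs, 4, init_params=fitted_500.params, max_iter=200)
        base = fit_em(Y, specs, 4, init_params=fitted_500.params, max_iter=200)
        assert refit.neg_loglik == pytest.approx(base.neg_loglik, abs=1e-10)
        for name in base.params.means:
            np.testing.assert_allclose(
                refit.params.means[name], base.params.means[name], atol=1e-10
            )
        np.testing.assert_allclose(refit.params.mixing, base.params.mixing, atol=1e-10)
        # the appended rows sit at the prior in the expanded posterior
        np.testing.assert_allclose(
            refit.posterior[-10:], np.tile(refit.params.mixing, (10, 1)), atol=1e-12
        )

    def test_two_class_gaussian_beats_grid_oracle(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(-1, 1, 60), rng.normal(2, 1, 40)])
        spec = [VariableSpec("g", "gaussian")]
        fit = fit_em(y[:, None], spec, K=2, n_restarts=5, seed=0, tol=1e-10)

        def grid_ll(pi, m1, m2, s2):
            d = pi * norm.pdf(y, m1, np.sqrt(s2)) + (1 - pi) * norm.pdf(y, m2, np.sqrt(s2))
            return np.log(d).sum()

        best = max(
            grid_ll(pi, m1, m2, s2)
            for pi in np.linspace(0.2, 0.8, 13)
            for m1 in np.linspace(-2, 0, 11)
            for m2 in np.linspace(1, 3, 11)
            for s2 in np.linspace(0.5, 2.0, 10)
        )
        assert -fit.neg_loglik >= best - 1e-3

    def test_needs_more_rows_than_classes(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((3, 1)), [VariableSpec("g", "gaussian")], K=3)


class TestCountingAndBIC:
    def test_default_spec_closed_form_16K_plus_25(self):
        specs = default_indicator_specs()
        assert len(specs) == 15
        for K in range(1, 11):
            assert count_parameters(specs, K) == 16 * K + 25

    @pytest.mark.parametrize("K, expected", [(2, 57), (3, 73), (4, 89), (5, 105)])
    def test_published_parameter_counts(self, K, expected):
        assert count_parameters(default_indicator_specs(), K) == expected

    def test_single_gaussian_one_class(self):
        assert count_parameters([VariableSpec("g", "gaussian")], 1) == 2

    def test_reduced_indicator_sets_are_consistent(self):
        minus_iq = default_indicator_specs("minus_iq")
        assert len(minus_iq) == 13
        for K in (2, 4):
            assert count_parameters(minus_iq, K) == 14 * K + 23

    @pytest.mark.parametrize(
        "negll, p, expected",
        [(1555.64, 57, 3385.57), (1457.23, 73, 3265.75),
         (1385.68, 89, 3199.64), (1363.35, 105, 3231.98)],
    )
    def test_published_bic_values(self, negll, p, expected):
        assert bic(negll, p, 123) == pytest.approx(expected, abs=0.01)

    def test_degenerate_bic(self):
        assert bic(0.0, 0, 1) == 0.0


class TestEnumerateClasses:
    def test_one_class_data_chooses_one(self):
        chosen_count = 0
        spec = [VariableSpec("g", "gaussian"), VariableSpec("h", "gaussian")]
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Y = rng.normal(size=(150, 2))
            _, chosen, _ = enumerate_classes(
                Y, spec, [1, 2, 3], n_restarts=2, seed=seed
            )
            chosen_count += chosen == 1
        assert chosen_count >= 3  # majority of replicates

    def test_table_nparams_matches_count_parameters(self, processed_500):
        Y, specs, _ = processed_500
        table, chosen, _ = enumerate_classes(
            Y, specs, [2, 3], n_restarts=1, seed=0, max_iter=60
        )
        for K in (2, 3):
            assert table.loc[K, "n_params"] == count_parameters(specs, K)
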