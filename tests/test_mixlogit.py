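"""Mixed logit: probabilities, simulated likelihood, estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize
from scipy.stats import norm

import vaxdce as vd
from vaxdce.errors import IdentifiabilityError, InvalidSpecError
from vaxdce.mixlogit import ModelSpec, choice_probabilities, simulated_loglik


class TestChoiceProbabilities:
    def test_symmetric_pair(self):
        assert np.allclose(choice_probabilities([0.0, 0.0]), [0.5, 0.5])

    def test_published_constant_vs_optout(self):
        p = choice_probabilities([2.804, 0.0])
        assert np.round(p, 4).tolist() == [0.9429, 0.0571]

    def test_translation_invariance(self):
        v = np.array([1.0, 1.5, 0.5])
        assert np.allclose(choice_probabilities(v), choice_probabilities(v + 100))

    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_normalization_and_shift_invariance(self, utils):
        p = choice_probabilities(utils)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)
        assert np.allclose(p, choice_probabilities(np.array(utils) - 7.5), atol=1e-12)

    def test_overflow_safe(self):
        p = choice_probabilities([1000.0, 0.0])
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(InvalidSpecError):
            choice_probabilities([])
        with pytest.raises(InvalidSpecError):
            choice_probabilities([np.nan, 0.0])


def _independent_cl_loglik(table, means):
    """Closed-form conditional logit log-likelihood, written independently
    of the package internals (plain pandas loop)."""
    cols = table.coefficient_columns
    ll = 0.0
    for _, grp in table.data.groupby(["respondent_id", "task_id"]):
        v = grp[cols].to_numpy() @ means
        v = v - v.max()
        p = np.exp(v) / np.exp(v).sum()
        ll += np.log(p[grp["chosen"].to_numpy() == 1][0])
    return ll


class TestSimulatedLoglik:
    def test_uniform_case_is_log_one_third(self, mini_spec, mini_design):
        pop = np.zeros((1, 2))
        table = vd.simulate_choices(pop, mini_design, mini_spec, seed=3)
        one_task = vd.LongChoiceTable(
            table.data[table.data.task_id == 1].reset_index(drop=True), mini_spec)
        ll = simulated_loglik(np.zeros(2), [], one_task,
                              ModelSpec(random_coefficients=(), n_draws=1))
        assert ll == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_zero_sd_equals_conditional_logit_any_draw_count(self, cl_study):
        means = vd.hz_true_parameters(0.0).means
        oracle = _independent_cl_loglik(cl_study.table, means)
        for draws in (1, 9):
            ll = simulated_loglik(means, np.zeros(16), cl_study.table,
                                  ModelSpec(n_draws=draws, seed=1))
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_matches_adaptive_quadrature_on_tiny_mixed_instance(
            self, mini_spec, mini_design):
        pop = np.array([[0.5, 1.0], [0.5, 1.0]])
        table = vd.simulate_choices(pop, mini_design, mini_spec, seed=1)
        c, mu, s = 0.4, 0.8, 0.6
        ll_sim = simulated_loglik(
            np.array([c, mu]), np.array([s]), table,
            ModelSpec(random_coefficients=("x_b",), n_draws=10000, seed=77))

        cols = ["const", "x_b"]
        ll_quad = 0.0
        for rid, grp in table.data.groupby("respondent_id"):
            def prod_p(b):
                out = 1.0
                for _, g in grp.groupby("task_id"):
                    v = g[cols].to_numpy() @ np.array([c, b])
                    p = np.exp(v - v.max())
                    p /= p.sum()
                    out *= p[g["chosen"].to_numpy() == 1][0]
                return out
            val, _ = integrate.quad(lambda b: prod_p(b) * norm.pdf(b, mu, s),
                                    mu - 10 * s, mu + 10 * s, limit=200)
            ll_quad += np.log(val)
        assert ll_sim == pytest.approx(ll_quad, abs=1e-3)

    def test_nonfinite_parameters_rejected(self, cl_study):
        with pytest.raises(InvalidSpecError):
            simulated_loglik(np.full(16, np.nan), np.zeros(16), cl_study.table)


class TestFit:
    def test_conditional_logit_recovers_truth_within_ci(self, cl_result, fixed_truth):
        """Coverage property: at n=400, >=14/16 coefficients inside their 95% CI."""
        summary = cl_result.summary()
        inside = 0
        for name, true in zip(fixed_truth.names, fixed_truth.means):
            row = summary[summary.term == name].iloc[0]
            inside += row.ci_low <= true <= row.ci_high
        assert inside >= 14

    def test_gradient_vanishes_at_cl_optimum(self, cl_study, cl_result):
        from vaxdce.mixlogit import _build_panel, _loglik_parts
        panel = _build_panel(cl_study.table)
        _, g, _ = _loglik_parts(cl_result.means, panel, np.array([], dtype=int),
                                np.zeros((panel.R, 1, 0)), want_grad=True)
        # score in standardized covariate units (the optimizer's metric):
        # beta_std = beta * s, so dLL/dbeta_std = (dLL/dbeta) / s
        scale = panel.X[panel.alt_mask].std(axis=0)
        assert np.abs(g / scale).max() < 1e-3

    def test_cl_fit_matches_independent_optimizer(self, hz_spec, hz_design, fixed_truth):
        """Dual-route check: same small dataset, likelihood and optimizer
        written independently in the test."""
        pop = vd.draw_population(fixed_truth, 150, seed=41)
        table = vd.simulate_choices(pop, hz_design, hz_spec, seed=42)
        ours = vd.fit_mixed_logit(table, vd.CONDITIONAL_LOGIT)

        cols = table.coefficient_columns
        groups = [(g[cols].to_numpy(), int(np.flatnonzero(g["chosen"].to_numpy())[0]))
                  for _, g in table.data.groupby(["respondent_id", "task_id"])]

        def negll(beta):
            out = 0.0
            for X, ch in groups:
                v = X @ beta
                v = v - v.max()
                out -= v[ch] - np.log(np.exp(v).sum())
            return out

        ref = optimize.minimize(negll, np.zeros(len(cols)), method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 2000})
        assert abs(-ref.fun - ours.loglik) < 0.1
        assert np.abs(ref.x - ours.means).max() < 0.05

    def test_same_seed_bit_identical(self, hz_spec, hz_design, fixed_truth):
        pop = vd.draw_population(vd.hz_true_parameters(0.3), 80, seed=51)
        table = vd.simulate_choices(pop, hz_design, hz_spec, seed=52)
        model = ModelSpec(random_coefficients=("const",), n_draws=50, seed=12345)
        a = vd.fit_mixed_logit(table, model)
        b = vd.fit_mixed_logit(table, model)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.sds, b.sds)
        assert a.loglik == b.loglik

    def test_row_order_invariance(self, hz_spec, hz_design, fixed_truth):
        pop = vd.draw_population(fixed_truth, 60, seed=61)
        table = vd.simulate_choices(pop, hz_design, hz_spec, seed=62)
        shuffled = table.data.sample(frac=1.0, random_state=0)
        shuffled = shuffled.sort_values(["respondent_id", "task_id"],
                                        kind="stable").reset_index(drop=True)
        a = vd.fit_mixed_logit(table, vd.CONDITIONAL_LOGIT)
        b = vd.fit_mixed_logit(vd.LongChoiceTable(shuffled, hz_spec),
                               vd.CONDITIONAL_LOGIT)
        assert np.allclose(a.means, b.means, atol=1e-6)

    def test_nonvarying_covariate_named_in_error(self, cl_study, hz_spec):
        df = cl_study.table.data.copy()
        df["duration_5"] = 0.0
        with pytest.raises(IdentifiabilityError, match="duration_5"):
            vd.fit_mixed_logit(vd.LongChoiceTable(df, hz_spec), vd.CONDITIONAL_LOGIT)

    def test_vcov_symmetric_psd_and_ci_convention(self, cl_result):
        v = cl_result.vcov
        assert np.allclose(v, v.T)
        assert np.linalg.eigvalsh(v).min() > -1e-10
        s = cl_result.summary()
        assert np.allclose(s.ci_high - s.estimate, 1.959963984540054 * s.se)

    def test_doubling_draws_does_not_worsen_likelihood_noise(
            self, hz_spec, hz_design):
        """Variance of the simulated likelihood across draw seeds shrinks
        (or at least does not grow) when draws double."""
        params = vd.hz_true_parameters(0.5)
        pop = vd.draw_population(params, 60, seed=71)
        table = vd.simulate_choices(pop, hz_design, hz_spec, seed=72)
        sds = params.sds[:-1]  # non-price random
        names = tuple(c for c in hz_spec.coefficient_columns() if c != "price")
        def spread(draws):
            lls = [simulated_loglik(params.means, sds, table,
                                    ModelSpec(random_coefficients=names,
                                              n_draws=draws, draw_scheme="pseudo",
                                              seed=s))
                   for s in range(1, 9)]
            return np.var(lls)
        assert spread(64) <= spread(8)
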