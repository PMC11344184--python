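"""Willingness-to-pay ratios and bootstrap confidence intervals."""

import numpy as np
import pandas as pd
import pytest

import vaxdce as vd
from vaxdce.errors import InvalidSpecError, UndefinedWTPError
from vaxdce.mixlogit import CONDITIONAL_LOGIT, EstimationResult, ModelSpec
from vaxdce.wtp import WTPTable, bundle_wtp


def _result_with(means, hz_spec, vcov=None):
    names = hz_spec.coefficient_columns()
    means = np.asarray(means, dtype=float)
    K = len(names)
    vcov = np.zeros((K, K)) if vcov is None else vcov
    return EstimationResult(
        coef_names=list(names), random_names=[], means=means,
        sds=np.array([]), se=np.sqrt(np.diag(vcov)), vcov=vcov,
        loglik=0.0, converged=True, n_respondents=1, n_tasks=1, n_rows=1,
        model=CONDITIONAL_LOGIT, study_spec=hz_spec)


@pytest.fixture
def published_means(hz_spec):
    means = np.array([vd.HZ_MEAN_COEFFICIENTS[c]
                      for c in hz_spec.coefficient_columns()])
    return _result_with(means, hz_spec)


class TestPointWTP:
    def test_zero_coefficient_gives_zero_wtp(self, hz_spec):
        means = np.zeros(16)
        means[-1] = -0.002
        w = vd.compute_wtp(_result_with(means, hz_spec))
        assert (w.table["wtp"] == 0).all()

    def test_effectiveness_90_ratio(self, published_means):
        # 2.746 / 0.00282 — the published monetary value is ~973.7 CN¥
        w = vd.compute_wtp(published_means)
        assert w.value("effectiveness_90") == pytest.approx(973.8, abs=0.5)

    def test_scale_invariance(self, published_means, hz_spec):
        w1 = vd.compute_wtp(published_means)
        scaled = _result_with(published_means.means * 3.0, hz_spec)
        w3 = vd.compute_wtp(scaled)
        assert np.allclose(w1.table["wtp"], w3.table["wtp"])

    def test_sign_follows_coefficient(self, published_means):
        w = vd.compute_wtp(published_means)
        assert w.value("origin_imported") < 0
        assert w.value("duration_20") > 0

    def test_monotone_in_level_coefficient(self, published_means):
        w = vd.compute_wtp(published_means)
        assert (w.value("effectiveness_90") > w.value("effectiveness_75")
                > w.value("effectiveness_60"))

    def test_zero_price_is_undefined(self, hz_spec):
        means = np.ones(16)
        means[-1] = 0.0
        with pytest.raises(UndefinedWTPError):
            vd.compute_wtp(_result_with(means, hz_spec))

    def test_positive_price_warns(self, hz_spec):
        means = np.ones(16)
        with pytest.warns(UserWarning, match="positive"):
            vd.compute_wtp(_result_with(means, hz_spec))


class TestBundles:
    def test_component_sum_equals_sum_of_coefficients(self, published_means):
        """Linearity: summed component WTPs = WTP of summed coefficients."""
        w = vd.compute_wtp(published_means)
        total = bundle_wtp(w, {"effectiveness_90": 1, "duration_20": 1})
        beta_sum = (published_means.mean("effectiveness_90")
                    + published_means.mean("duration_20"))
        assert total == pytest.approx(beta_sum / (-published_means.mean("price")))


class TestConfidenceIntervals:
    def test_zero_vcov_gives_zero_width(self, published_means):
        w = vd.wtp_confidence_intervals(published_means, replicates=200, seed=1)
        assert np.allclose(w.table["ci_low"], w.table["wtp"])
        assert np.allclose(w.table["ci_high"], w.table["wtp"])

    def test_same_seed_identical_intervals(self, cl_result):
        a = vd.wtp_confidence_intervals(cl_result, replicates=300, seed=5)
        b = vd.wtp_confidence_intervals(cl_result, replicates=300, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_interval_contains_point_estimate(self, cl_result):
        w = vd.wtp_confidence_intervals(cl_result, replicates=1000, seed=6)
        assert ((w.table["ci_low"] <= w.table["wtp"])
                & (w.table["wtp"] <= w.table["ci_high"])).all()

    def test_few_replicates_warns(self, cl_result):
        with pytest.warns(UserWarning, match="replicates"):
            vd.wtp_confidence_intervals(cl_result, replicates=50, seed=7)

    def test_nonparametric_requires_data_and_runs(self):
        from vaxdce.design import AttributeSpec, StudyDesignSpec
        spec = StudyDesignSpec((
            AttributeSpec("x", ("a", "b")),
            AttributeSpec("price", ("0", "100"), coding="continuous",
                          numeric_values=(0.0, 100.0)),
        ), n_tasks=4, n_blocks=1)
        design = vd.build_choice_design(spec, run_size=4, seed=1)
        pop = np.tile([0.5, 1.0, -0.02], (60, 1))
        table = vd.simulate_choices(pop, design, spec, seed=8)
        res = vd.fit_mixed_logit(table, CONDITIONAL_LOGIT)
        with pytest.raises(InvalidSpecError):
            vd.wtp_confidence_intervals(res, method="nonparametric",
                                        replicates=100, seed=9)
        w = vd.wtp_confidence_intervals(res, method="nonparametric",
                                        replicates=100, seed=9, data=table)
        assert w.value("x_b") == pytest.approx(res.mean("x_b") / -res.mean("price"))
        assert (w.table["ci_low"] <= w.table["wtp"]).all()
        assert (w.table["wtp"] <= w.table["ci_high"]).all()

    def test_currency_conversion_is_display_only(self, published_means):
        w = vd.compute_wtp(published_means)
        usd = w.converted(1 / 6.7)
        assert usd["wtp"].iloc[0] == pytest.approx(w.table["wtp"].iloc[0] / 6.7)
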