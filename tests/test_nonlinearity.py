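import numpy as np
import pytest
from scipy import stats

from ozmort import (
    ModelSpec,
    classify_shape,
    compare_models,
    fit_linear_model,
    fit_spline_model,
    select_lag,
)
from ozmort.nonlinearity import CurveFit, modal_lag
from ozmort.synthetic import ExposureEffect, SyntheticConfig, simulate_city


def _curve(grid, log_rr, p10=None, p90=None):
    grid = np.asarray(grid, float)
    return CurveFit(
        fit=None, grid=grid, log_rr=np.asarray(log_rr, float),
        se=np.zeros_like(grid), reference=float(grid[0]),
        exposure_percentiles=(
            p10 if p10 is not None else float(np.quantile(grid, 0.1)),
            p90 if p90 is not None else float(np.quantile(grid, 0.9)),
        ),
    )


class TestClassifyShape:
    def test_convex_interior_minimum_is_j_or_u(self):
        g = np.arange(10.0, 61.0)
        assert classify_shape(_curve(g, (g - 25) ** 2 / 1000)) == "J_or_U"

    def test_line_is_monotone(self):
        g = np.arange(10.0, 61.0)
        assert classify_shape(_curve(g, 0.001 * g)) == "monotone"

    def test_wiggle_is_other(self):
        g = np.arange(10.0, 61.0)
        assert classify_shape(_curve(g, 0.001 * np.sin(g / 3.0))) == "other"

    def test_flat_curve_is_other(self):
        g = np.arange(10.0, 61.0)
        assert classify_shape(_curve(g, np.zeros_like(g))) == "other"

    def test_narrow_grid_rejected(self):
        g = np.arange(10.0, 25.0)
        with pytest.raises(ValueError):
            classify_shape(_curve(g, g))


class TestCityComparison:
    def test_df1_spline_equals_linear_aic(self, null_city):
        cmp_ = compare_models(null_city, ModelSpec(df_o3=1))
        assert cmp_.delta_aic == pytest.approx(0.0, abs=1e-6)
        assert cmp_.p_value == 1.0

    def test_delta_aic_consistent_with_likelihoods(self, hockey_city, spec):
        cmp_ = compare_models(hockey_city, spec)
        # dAIC = 2(k_s - k_l) - 2(L_s - L_l); deviance diff = 2 x llf diff
        assert cmp_.deviance_diff == pytest.approx(
            cmp_.aic_linear - cmp_.aic_spline + 2 * cmp_.df, abs=1e-8
        )

    def test_hockey_truth_detected(self, hockey_city, spec):
        cmp_ = compare_models(hockey_city, spec)
        assert cmp_.delta_aic < 0
        assert cmp_.shape == "J_or_U"
        assert cmp_.meets_criteria

    def test_spline_curve_reference_is_zero(self, hockey_city, spec):
        curve = fit_spline_model(hockey_city, spec)
        ref_val = np.interp(curve.reference, curve.grid, curve.log_rr)
        assert abs(ref_val) < 5e-4  # reference sits between grid points
        assert np.all(np.diff(curve.grid) > 0)

    def test_linear_slope_recovery(self):
        """Injected log-linear slope is recovered across seeds."""
        betas, ses = [], []
        for seed in range(12):
            s = simulate_city(
                SyntheticConfig(n_days=1461, seed=300 + seed,
                                exposure=ExposureEffect.linear(0.001)), 0
            )
            fit = fit_linear_model(s, ModelSpec())
            betas.append(fit.coef("o3"))
            ses.append(fit.se("o3"))
        mean_beta = np.mean(betas)
        assert mean_beta == pytest.approx(0.001, abs=2.5 * np.std(betas) / np.sqrt(12))
        # and the average estimate is within ~20% of truth
        assert 0.0008 < mean_beta < 0.0012

    def test_null_effect_covered_by_confidence_interval(self):
        hits = 0
        for seed in range(15):
            s = simulate_city(SyntheticConfig(n_days=1096, seed=500 + seed), 0)
            fit = fit_linear_model(s, ModelSpec())
            hits += abs(fit.coef("o3")) < 2 * fit.se("o3")
        assert hits >= 12  # ~95% nominal coverage, small-sample slack

    def test_deviance_p_uniform_under_linear_truth(self):
        """Spline-vs-linear p-values are ~Uniform(0,1) when the truth is
        linear (chi-square calibration of the deviance test)."""
        ps = []
        for seed in range(60):
            s = simulate_city(
                SyntheticConfig(n_days=1096, seed=900 + seed,
                                exposure=ExposureEffect.linear(0.0008)), 0
            )
            ps.append(compare_models(s, ModelSpec()).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSelectLag:
    def test_single_candidate_returned(self, null_city, spec):
        chosen, table = select_lag(null_city, spec, [(0,)])
        assert chosen == (0,)
        assert set(table) == {(0,)}

    def test_most_negative_delta_aic_wins(self, hockey_city, spec):
        # the generative ozone effect acts on the lag0-1 average, so lag0-1
        # should beat a long misaligned window
        chosen, table = select_lag(hockey_city, spec, [(0, 1), (0, 1, 2, 3, 4, 5, 6, 7)])
        assert chosen == (0, 1)
        assert table[(0, 1)] < table[(0, 1, 2, 3, 4, 5, 6, 7)]

    def test_tie_breaks_to_smaller_lag_set(self):
        assert modal_lag([(0, 1), (0, 2), (0, 1), (0, 2)]) == (0, 1)
        assert modal_lag([(0, 3), (0, 1), (0, 1), (0, 3), (0, 3)]) == (0, 3)
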