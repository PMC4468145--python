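import copy

import numpy as np
import pytest
from scipy import optimize
from scipy.special import gammaln

from ozmort import build_design, deviance_test, fit_poisson, model_aic
from ozmort.design import DesignMatrix
from ozmort.glm import NotConvergedError


def _toy_design(X, y, offset=None, columns=None):
    import pandas as pd

    n = len(y)
    return DesignMatrix(
        y=np.asarray(y, float), X=np.asarray(X, float),
        offset=np.zeros(n) if offset is None else np.asarray(offset, float),
        columns=columns or [f"c{i}" for i in range(np.asarray(X).shape[1])],
        blocks={}, dates=pd.date_range("2000-01-01", periods=n),
        exposure_values=np.zeros(n),
    )


class TestFitPoisson:
    def test_intercept_only_mle_is_log_mean(self):
        fit = fit_poisson(_toy_design(np.ones((3, 1)), [1, 2, 3]))
        assert fit.params[0] == pytest.approx(np.log(2.0), abs=1e-10)

    def test_offset_shifts_intercept(self):
        pop = 5.0e5
        y = [10, 12, 8, 10]
        fit = fit_poisson(_toy_design(np.ones((4, 1)), y, offset=np.log(pop) * np.ones(4)))
        assert fit.params[0] == pytest.approx(np.log(np.mean(y) / pop), abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_likelihood_maximization(self, seed):
        """IRLS solution equals direct numerical maximisation of the Poisson
        log-likelihood on a random 50x3 problem."""
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        beta_true = np.array([1.0, 0.3, -0.2])
        offset = rng.normal(0, 0.1, 50)
        y = rng.poisson(np.exp(X @ beta_true + offset)).astype(float)

        fit = fit_poisson(_toy_design(X, y, offset=offset))

        def negll(b):
            eta = X @ b + offset
            return -(y @ eta - np.exp(eta).sum())

        res = optimize.minimize(negll, np.zeros(3), method="BFGS",
                                options={"gtol": 1e-10})
        np.testing.assert_allclose(fit.params, res.x, atol=1e-6)

    def test_matches_statsmodels(self, null_city, spec):
        """Independent cross-check of the whole design+fit path."""
        import statsmodels.api as sm

        dm = build_design(null_city, spec)
        fit = fit_poisson(dm)
        smfit = sm.GLM(
            dm.y, dm.X, family=sm.families.Poisson(), offset=dm.offset
        ).fit()
        np.testing.assert_allclose(fit.params, smfit.params, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(fit.bse, smfit.bse, rtol=1e-4)
        assert fit.llf == pytest.approx(smfit.llf, abs=1e-5)
        assert fit.deviance == pytest.approx(smfit.deviance, abs=1e-5)

    def test_aic_identity_to_machine_precision(self, null_city, spec):
        fit = fit_poisson(build_design(null_city, spec))
        assert fit.aic == 2 * fit.k - 2 * fit.llf  # exact, not approx

    def test_llf_includes_factorial_constant(self):
        y = np.array([3.0, 7.0, 2.0])
        fit = fit_poisson(_toy_design(np.ones((3, 1)), y))
        mu = np.mean(y)
        expected = np.sum(y * np.log(mu) - mu - gammaln(y + 1))
        assert fit.llf == pytest.approx(expected, abs=1e-10)

    def test_offset_equivariance(self, null_city, spec):
        dm = build_design(null_city, spec)
        f1 = fit_poisson(dm)
        dm2 = copy.copy(dm)
        dm2.offset = dm.offset + np.log(3.0)
        f2 = fit_poisson(dm2)
        assert f1.params[0] - f2.params[0] == pytest.approx(np.log(3.0), abs=1e-7)
        np.testing.assert_allclose(f1.params[1:], f2.params[1:], atol=1e-8)

    def test_intercept_score_equation(self, null_city, spec):
        """Mean fitted count equals mean observed count (score equation)."""
        dm = build_design(null_city, spec)
        fit = fit_poisson(dm)
        assert abs(fit.mu.mean() - dm.y.mean()) < 1e-8

    def test_deviance_nonincreasing_with_added_columns(self, rng):
        X = np.column_stack([np.ones(80), rng.standard_normal((80, 2))])
        y = rng.poisson(np.exp(0.5 + 0.2 * X[:, 1])).astype(float)
        d_small = fit_poisson(_toy_design(X[:, :2], y)).deviance
        d_big = fit_poisson(_toy_design(X, y)).deviance
        assert d_big <= d_small + 1e-10

    def test_singular_design_flagged_not_silent(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), x, x])  # exactly collinear
        y = rng.poisson(np.exp(1 + 0.1 * x)).astype(float)
        fit = fit_poisson(_toy_design(X, y))
        assert not fit.converged
        assert "singular" in fit.diagnostic


class TestAicAndDevianceTest:
    @pytest.mark.parametrize("k,llf,expected", [(3, -100.0, 206.0), (0, 0.0, 0.0)])
    def test_aic_formula(self, k, llf, expected):
        from ozmort.glm import FitResult

        fit = FitResult(
            params=np.zeros(k), bse=np.zeros(k), cov=np.zeros((k, k)),
            columns=[], llf=llf, deviance=0.0, k=k, aic=2 * k - 2 * llf,
            n=10, converged=True, n_iter=1,
        )
        assert model_aic(fit) == expected

    def test_unconverged_fit_rejected(self):
        from ozmort.glm import FitResult

        bad = FitResult(
            params=np.zeros(1), bse=np.zeros(1), cov=np.zeros((1, 1)),
            columns=[], llf=-1.0, deviance=0.0, k=1, aic=4.0,
            n=10, converged=False, n_iter=100,
        )
        with pytest.raises(NotConvergedError):
            model_aic(bad)

    def test_self_comparison_p_is_one(self, null_city, spec):
        fit = fit_poisson(build_design(null_city, spec))
        assert deviance_test(fit, fit) == 1.0

    def test_chi_square_reference(self):
        """Statistic 3.84 on 1 df sits at the 5% point."""
        from ozmort.glm import FitResult

        def mk(dev, k):
            return FitResult(
                params=np.zeros(k), bse=np.zeros(k), cov=np.zeros((k, k)),
                columns=[], llf=0.0, deviance=dev, k=k, aic=0.0,
                n=50, converged=True, n_iter=1,
            )

        p = deviance_test(mk(103.84, 2), mk(100.0, 3))
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_row_mismatch_rejected(self, null_city, spec):
        fit = fit_poisson(build_design(null_city, spec))
        other = copy.copy(fit)
        other.n = fit.n - 1
        with pytest.raises(ValueError):
            deviance_test(other, fit)
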