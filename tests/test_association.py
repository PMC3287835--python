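import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from qtdesign.association import fit_glm_reverse, fit_linear, wald_test


def _wls_oracle(y, x, w, mode):
    """Direct matrix-formula WLS: beta, and cov under the requested mode."""
    X = np.column_stack([np.ones(len(x)), x])
    A_inv = np.linalg.inv(X.T @ np.diag(w) @ X)
    beta = A_inv @ X.T @ np.diag(w) @ y
    e = y - X @ beta
    if mode == "classical":
        cov = (w * e**2).sum() / (len(y) - 2) * A_inv
    else:
        meat = X.T @ np.diag(w**2 * e**2) @ X
        cov = A_inv @ meat @ A_inv
    return beta, cov


def _glm_mle_oracle(outcome, y, family):
    """Brute-force MLE: coarse grid start + high-precision quasi-Newton."""
    X = np.column_stack([np.ones(len(y)), y])

    def negll(beta):
        eta = X @ beta
        if family == "binomial":
            return float(np.sum(np.log1p(np.exp(eta)) - outcome * eta))
        return float(np.sum(np.exp(eta) - outcome * eta))

    best = None
    for b0 in np.linspace(-2, 2, 9):
        for b1 in np.linspace(-2, 2, 9):
            r = optimize.minimize(negll, [b0, b1], method="BFGS",
                                  options={"gtol": 1e-12, "maxiter": 500})
            if best is None or r.fun < best.fun:
                best = r
    return best.x


class TestFitLinear:
    def test_perfect_fit_zero_se(self):
        x = np.arange(10.0)
        res = fit_linear(2 * x, x)
        assert res.coefficient == pytest.approx(2.0)
        assert res.se == pytest.approx(0.0, abs=1e-8)

    def test_equal_weights_match_unweighted_estimate(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = fit_linear(y, x)
        b = fit_linear(y, x, weights=np.full(30, 3.7))
        assert b.coefficient == pytest.approx(a.coefficient, abs=1e-12)

    @pytest.mark.parametrize("mode", ["classical", "design_sandwich"])
    def test_matches_matrix_formula_oracle(self, rng, mode):
        y, x = rng.normal(size=8), rng.normal(size=8)
        w = rng.uniform(0.5, 3.0, 8)
        res = fit_linear(y, x, weights=w, variance_mode=mode)
        beta, cov = _wls_oracle(y, x, w, mode)
        assert res.coefficient == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_unweighted_sandwich_matches_statsmodels_hc0(self, rng):
        import statsmodels.api as sm

        x, y = rng.normal(size=40), rng.normal(size=40)
        res = fit_linear(y, x, variance_mode="design_sandwich")
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC0")
        assert res.coefficient == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(sm_fit.bse[1], abs=1e-10)

    def test_sandwich_close_to_classical_when_homoskedastic(self, rng):
        """Both variance estimators are consistent for iid Gaussian errors."""
        x = rng.normal(size=321)
        y = 0.5 * x + rng.normal(size=321)
        a = fit_linear(y, x, variance_mode="classical")
        b = fit_linear(y, x, variance_mode="design_sandwich")
        assert abs(b.se - a.se) / a.se < 0.15

    def test_collinear_predictor_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear(np.arange(5.0), np.ones(5))

    def test_nonpositive_weight_rejected(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_linear(y, x, weights=np.r_[0.0, np.ones(9)])


class TestFitGlmReverse:
    def test_constant_poisson_outcome_gives_zero_slope(self, rng):
        y = rng.normal(size=50)
        res = fit_glm_reverse(np.full(50, 3), y - y.mean(), "poisson")
        assert res.converged
        assert res.coefficient == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_matches_brute_force_mle(self, rng, family):
        y = rng.normal(size=10)
        if family == "binomial":
            outcome = rng.integers(0, 2, 10).astype(float)
        else:
            outcome = rng.poisson(1.0, 10).astype(float)
        outcome[0] = 1.0  # keep outcomes non-degenerate
        res = fit_glm_reverse(outcome, y, family)
        oracle = _glm_mle_oracle(outcome, y, family)
        assert res.converged
        assert res.coefficient == pytest.approx(oracle[1], abs=1e-6)

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_matches_statsmodels_glm(self, rng, family):
        import statsmodels.api as sm

        y = rng.normal(size=60)
        mu = 1 / (1 + np.exp(-0.8 * y))
        if family == "binomial":
            outcome = rng.binomial(1, mu).astype(float)
            fam = sm.families.Binomial()
        else:
            outcome = rng.poisson(np.exp(0.3 * y)).astype(float)
            fam = sm.families.Poisson()
        res = fit_glm_reverse(outcome, y, family)
        sm_fit = sm.GLM(outcome, sm.add_constant(y), family=fam).fit()
        assert res.coefficient == pytest.approx(sm_fit.params[1], abs=1e-7)
        assert res.se == pytest.approx(sm_fit.bse[1], rel=1e-4)

    def test_complete_separation_flagged(self):
        y = np.r_[np.linspace(-3, -1, 8), np.linspace(1, 3, 8)]
        outcome = (y > 0).astype(float)
        res = fit_glm_reverse(outcome, y, "binomial")
        assert not res.converged

    def test_degenerate_outcomes_rejected(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_glm_reverse(np.zeros(10), y, "poisson")
        with pytest.raises(ValueError):
            fit_glm_reverse(np.ones(10), y, "binomial")
        with pytest.raises(ValueError):
            fit_glm_reverse(np.array([0, 1, 2, 0, 1, 0, 0, 1, 0, 1]), y, "binomial")

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_poisson_irls_agrees_with_mle_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        outcome = rng.poisson(np.exp(0.2 * y), 12).astype(float)
        if outcome.sum() == 0:
            outcome[0] = 1.0
        res = fit_glm_reverse(outcome, y, "poisson")
        oracle = _glm_mle_oracle(outcome, y, "poisson")
        assert res.coefficient == pytest.approx(oracle[1], abs=1e-5)


class TestWaldTest:
    def test_null_point(self):
        stat, p = wald_test(0.0, 1.0, "normal")
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_zero_se_sentinel(self):
        stat, p = wald_test(1.0, 0.0, "normal")
        assert np.isinf(stat) and p == 0.0

    def test_t_reference_reproduces_printed_pair(self):
        """statistic 5.18 with 319 df prints as p = 4e-7."""
        _, p = wald_test(5.18, 1.0, "t", df=319)
        assert 3.5e-7 <= p <= 4.5e-7

    def test_normal_reference_reproduces_printed_pair(self):
        """statistic 5.59 against the standard normal prints as p = 2e-8."""
        _, p = wald_test(5.59, 1.0, "normal")
        assert 1.5e-8 <= p <= 2.5e-8

    def test_t_reference_requires_df(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 1.0, "t")
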