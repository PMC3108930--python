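import math

import numpy as np
import pytest

from domainprio.bayes import (
    LOG10,
    RegressionPriors,
    bayes_factor,
    bf_quadrature_oracle,
    limit_log10_bf,
    limit_log10_bf_many,
    log_marginal_alternative,
    log_marginal_null,
    log_marginal_null_quadrature,
    r_squared,
)

FINITE = RegressionPriors(mu0=(0.0, 0.0), sigma_mu_sq=1.0, sigma1_sq=1.0,
                          n0=1.0, sigma0_sq=1.0)


class TestMarginalsAgainstQuadrature:
    def test_alternative_matches_dense_integration(self):
        rng = np.random.default_rng(10)
        for _ in range(3):
            y, x = rng.normal(size=5), rng.normal(size=5)
            exact = log_marginal_alternative(y, x, FINITE)
            quad = bf_quadrature_oracle(y, x, FINITE)
            assert exact == pytest.approx(quad, abs=1e-4)

    def test_null_matches_dense_integration(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            y = rng.normal(size=5)
            exact = log_marginal_null(y, FINITE)
            quad = log_marginal_null_quadrature(y, FINITE)
            assert exact == pytest.approx(quad, abs=1e-4)

    def test_length_three_high_accuracy(self):
        # finer grid pushes the trapezoid error below 1e-6 log units
        y = np.array([0.3, -1.1, 0.8])
        x = np.array([1.0, -0.5, 0.2])
        exact = log_marginal_alternative(y, x, FINITE)
        quad = bf_quadrature_oracle(y, x, FINITE, n_coef=201, n_logvar=401)
        assert exact == pytest.approx(quad, abs=1e-6)

    def test_quadrature_refinement_converges(self):
        y = np.array([0.5, -0.2, 1.3, 0.1, -0.9])
        x = np.array([1.0, 0.3, -0.7, 0.2, 0.9])
        coarse = bf_quadrature_oracle(y, x, FINITE, n_coef=121, n_logvar=241)
        fine = bf_quadrature_oracle(y, x, FINITE, n_coef=181, n_logvar=361)
        assert coarse == pytest.approx(fine, abs=1e-5)

    def test_sign_symmetry_of_slope_prior(self):
        y = np.array([0.4, -0.4, 1.0, -1.0, 0.0])
        x = np.array([1.0, 2.0, -1.0, 0.5, 0.3])
        a = bf_quadrature_oracle(y, x, FINITE)
        b = bf_quadrature_oracle(y, -x, FINITE)
        assert a == pytest.approx(b, abs=1e-7)


class TestNullMarginalProperties:
    def test_permutation_invariant(self):
        y = np.array([0.3, 1.2, -0.7, 0.05])
        assert log_marginal_null(y, FINITE) == pytest.approx(
            log_marginal_null(y[::-1], FINITE))

    def test_all_zero_response_is_finite(self):
        assert math.isfinite(log_marginal_null(np.zeros(4), FINITE))

    def test_zero_predictor_equals_null_plus_slope_prior_noop(self):
        # x = 0 with mu0 = 0: the slope column carries no information
        y = np.array([0.7, -0.3, 0.4, 1.1])
        alt = log_marginal_alternative(y, np.zeros(4), FINITE)
        nul = log_marginal_null(y, FINITE)
        assert alt == pytest.approx(nul, abs=1e-10)


class TestLimitBayesFactor:
    def test_matches_finite_prior_limit_approach(self):
        rng = np.random.default_rng(12)
        near = RegressionPriors(sigma_mu_sq=1e6, n0=1e-6, sigma0_sq=1e-6)
        for _ in range(20):
            y, x = rng.normal(size=50), rng.normal(size=50)
            lim = limit_log10_bf(y, x)
            fin = (log_marginal_alternative(y, x, near)
                   - log_marginal_null(y, near)) / LOG10
            assert lim == pytest.approx(fin, rel=0.01)

    def test_location_invariance(self):
        rng = np.random.default_rng(13)
        y, x = rng.normal(size=30), rng.normal(size=30)
        base = limit_log10_bf(y, x)
        assert limit_log10_bf(y + 7.3, x) == pytest.approx(base, abs=1e-8)
        assert limit_log10_bf(y, x - 4.1) == pytest.approx(base, abs=1e-8)

    def test_constant_predictor_scores_zero(self):
        y = np.array([0.1, 0.9, -0.4])
        assert limit_log10_bf(y, np.full(3, 2.0)) == 0.0
        res = bayes_factor(y, np.full(3, 2.0))
        assert res.log10_bf == 0.0 and res.bf == 1.0

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bayes_factor(np.ones(5), np.arange(5.0))

    def test_monotone_in_signal_correlation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=80)
        noise = rng.normal(size=80)
        bfs = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            y = w * x + (1 - w) * noise
            bfs.append(limit_log10_bf(y, x))
        assert all(a <= b + 1e-9 for a, b in zip(bfs, bfs[1:]))

    def test_perfect_monotone_signal_gives_positive_evidence(self):
        from scipy.stats import rankdata

        from domainprio.profiles import inverse_normal_transform

        rng = np.random.default_rng(15)
        x = rng.uniform(size=50)
        y = inverse_normal_transform(rankdata(x))
        assert limit_log10_bf(y, x) > 0

    def test_no_overflow_on_long_strong_profiles(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=5000)
        y = x + 0.01 * rng.normal(size=5000)
        lb = limit_log10_bf(y, x)
        assert math.isfinite(lb) and lb > 300

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=25)
        xs = rng.normal(size=(6, 25))
        xs[2] = 3.14  # constant row
        many = limit_log10_bf_many(y, xs)
        singles = [limit_log10_bf(y, x) for x in xs]
        assert np.allclose(many, singles)


class TestBFScaleBehaviour:
    def test_bf_ratio_invariant_under_consistent_scaling(self):
        # scaling y and the residual-scale prior together shifts each
        # marginal but leaves their ratio unchanged (the coefficient priors
        # scale automatically because they are conditioned on sigma^2)
        rng = np.random.default_rng(18)
        y, x = rng.normal(size=6), rng.normal(size=6)
        c = 3.0
        scaled = RegressionPriors(mu0=(0.0, 0.0), sigma_mu_sq=1.0, sigma1_sq=1.0,
                                  n0=1.0, sigma0_sq=c**2)
        bf_base = (log_marginal_alternative(y, x, FINITE)
                   - log_marginal_null(y, FINITE))
        bf_scaled = (log_marginal_alternative(c * y, x, scaled)
                     - log_marginal_null(c * y, scaled))
        assert bf_base == pytest.approx(bf_scaled, abs=1e-8)
        assert log_marginal_null(c * y, scaled) != pytest.approx(
            log_marginal_null(y, FINITE), abs=1e-3)


class TestRSquared:
    def test_perfect_linear_fit(self):
        x = np.arange(5.0)
        assert r_squared(2 * x + 1, x) == pytest.approx(1.0)

    def test_constant_predictor_is_zero(self):
        assert r_squared(np.arange(4.0), np.ones(4)) == 0.0

    def test_matches_explicit_ols_oracle(self):
        rng = np.random.default_rng(19)
        y, x = rng.normal(size=10), rng.normal(size=10)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        rss, tss = resid @ resid, ((y - y.mean()) ** 2).sum()
        assert r_squared(y, x) == pytest.approx(1 - rss / tss)


class TestPriorsValidation:
    def test_limit_flag(self):
        assert RegressionPriors().is_limit
        assert not FINITE.is_limit

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            RegressionPriors(sigma1_sq=0.0)
        with pytest.raises(ValueError):
            RegressionPriors(n0=-1.0)

    def test_marginals_require_finite_priors(self):
        with pytest.raises(ValueError, match="finite priors"):
            log_marginal_alternative(np.zeros(3), np.zeros(3), RegressionPriors())
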