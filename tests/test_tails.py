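"""Exceedance curves, tail MLEs, family selection and Taylor's law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from ecomandala import (
    ExponentialTail,
    PowerLawTail,
    TaylorLaw,
    exceedance,
    fit_exponential,
    fit_powerlaw,
    select_family,
    taylor_exponent,
)
from ecomandala.errors import (
    DegenerateTailError,
    EmptyTableError,
    TooFewPointsError,
    TooFewTailPointsError,
)


def pareto_sample(rng, n, eps, xmin=1.0):
    """Inverse-CDF draws from the density ~ y^-eps above xmin."""
    return xmin * (1.0 - rng.random(n)) ** (-1.0 / (eps - 1.0))


def numeric_mle_powerlaw(tail, xmin):
    """Independent oracle: numeric maximizer of the power-law likelihood."""
    logs = np.log(tail / xmin)

    def nll(eps):
        return -(tail.size * np.log((eps - 1) / xmin) - eps * logs.sum())

    return minimize_scalar(
        nll, bounds=(1.0001, 30.0), method="bounded", options={"xatol": 1e-10}
    ).x


def numeric_mle_exponential(tail, xmin):
    shifted = tail - xmin

    def nll(lam):
        return -(tail.size * np.log(lam) - lam * shifted.sum())

    return minimize_scalar(
        nll, bounds=(1e-8, 1e4), method="bounded", options={"xatol": 1e-10}
    ).x


class TestExceedance:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3, 1, 2], {1: 1.0, 2: 2 / 3, 3: 1 / 3}),
            ([1, 1, 2], {1: 1.0, 2: 1 / 3}),
        ],
    )
    def test_direct_counts(self, values, expected):
        curve = exceedance(values)
        assert dict(zip(curve.y, curve.p)) == pytest.approx(expected)

    def test_empty_and_all_zero_raise(self):
        with pytest.raises(EmptyTableError):
            exceedance([])
        with pytest.raises(EmptyTableError):
            exceedance([0, 0])

    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_curve_invariants(self, values):
        curve = exceedance(values)
        assert curve.p[0] == 1.0
        assert np.all(np.diff(curve.p) <= 0)
        # n * p is an integer count of observations >= y
        n = len(values)
        np.testing.assert_allclose(curve.p * n, np.round(curve.p * n), atol=1e-9)


class TestPowerLawFit:
    def test_closed_form_examples(self):
        f = fit_powerlaw([np.e] * 4, xmin_policy="fixed", xmin=1.0, n_min=4)
        assert f.exponent == pytest.approx(2.0)
        f = fit_powerlaw([2, 4, 8], xmin_policy="fixed", xmin=2.0, n_min=3)
        assert f.exponent == pytest.approx(1 + 3 / (3 * np.log(2)))

    def test_recovers_generating_exponent(self, rng):
        values = pareto_sample(rng, 2000, eps=2.5)
        f = fit_powerlaw(values, xmin_policy="fixed", xmin=1.0)
        assert abs(f.exponent - 2.5) <= 0.1

    def test_matches_numeric_likelihood_maximizer(self, rng):
        for _ in range(10):
            values = pareto_sample(rng, 200, eps=rng.uniform(1.5, 4.0))
            f = fit_powerlaw(values, xmin_policy="fixed", xmin=1.0)
            assert abs(f.exponent - numeric_mle_powerlaw(np.sort(values), 1.0)) < 1e-6

    def test_scale_equivariance(self, rng):
        values = pareto_sample(rng, 300, eps=2.2, xmin=2.0)
        f1 = fit_powerlaw(values, xmin_policy="fixed", xmin=2.0)
        f2 = fit_powerlaw(values * 7.5, xmin_policy="fixed", xmin=15.0)
        assert f1.exponent == pytest.approx(f2.exponent, rel=1e-12)

    def test_ks_scan_targets_tail_of_mixed_sample(self, rng):
        # noisy head below 5 + clean Pareto tail above 5
        head = rng.uniform(0.1, 5.0, size=500)
        tail = pareto_sample(rng, 1500, eps=2.5, xmin=5.0)
        f = fit_powerlaw(np.concatenate([head, tail]), xmin_policy="ks_scan")
        assert f.xmin >= 2.0
        assert abs(f.exponent - 2.5) <= 0.25

    def test_refusals(self):
        with pytest.raises(TooFewTailPointsError):
            fit_powerlaw([1, 2, 3], xmin_policy="fixed", xmin=1.0, n_min=8)
        with pytest.raises(DegenerateTailError):
            fit_powerlaw([2.0] * 10, xmin_policy="fixed", xmin=2.0)

    def test_discrete_variant_close_to_continuous_for_large_counts(self, rng):
        values = np.rint(pareto_sample(rng, 1500, eps=2.5, xmin=50.0))
        cont = fit_powerlaw(values, xmin_policy="fixed", xmin=50.0)
        disc = fit_powerlaw(values, xmin_policy="fixed", xmin=50.0, discrete=True)
        assert abs(cont.exponent - disc.exponent) < 0.1


class TestExponentialFit:
    def test_closed_form_example(self):
        f = fit_exponential([1, 2, 3], xmin_policy="fixed", xmin=1.0, n_min=3)
        assert f.exponent == pytest.approx(1.0)

    def test_zero_spread_is_error(self):
        with pytest.raises(DegenerateTailError):
            fit_exponential([0.5] * 10, xmin_policy="fixed", xmin=0.5)

    def test_recovers_generating_rate(self, rng):
        values = rng.exponential(scale=1 / 5, size=2000)
        f = fit_exponential(values, xmin_policy="fixed", xmin=0.0)
        assert abs(f.exponent - 5.0) / 5.0 <= 0.05

    def test_matches_numeric_likelihood_maximizer(self, rng):
        for _ in range(10):
            values = rng.exponential(scale=rng.uniform(0.1, 10), size=150) + 1.0
            f = fit_exponential(values, xmin_policy="fixed", xmin=1.0)
            assert abs(f.exponent - numeric_mle_exponential(np.sort(values), 1.0)) < 1e-6

    def test_rate_scales_inversely(self, rng):
        values = rng.exponential(scale=0.5, size=400)
        f1 = fit_exponential(values, xmin_policy="fixed", xmin=0.0)
        f2 = fit_exponential(values * 4.0, xmin_policy="fixed", xmin=0.0)
        assert f2.exponent == pytest.approx(f1.exponent / 4.0, rel=1e-12)


class TestSelectFamily:
    def test_exponential_sample(self, rng):
        sel = select_family(rng.exponential(scale=1 / 5, size=2000))
        assert sel.verdict == "exponential"
        assert sel.delta_loglik < 0

    def test_powerlaw_sample(self, rng):
        sel = select_family(pareto_sample(rng, 2000, eps=2.5))
        assert sel.verdict == "powerlaw"
        assert sel.delta_loglik > 0

    def test_tiny_sample_inconclusive(self):
        assert select_family([1.0, 2.0, 3.0, 4.0, 5.0]).verdict == "inconclusive"

    def test_both_fits_share_xmin(self, rng):
        sel = select_family(pareto_sample(rng, 500, eps=2.0))
        assert sel.powerlaw.xmin == sel.exponential.xmin


class TestTaylorLaw:
    def test_exact_slope_two(self):
        # construct series with (mean, var) = (2,4), (4,16), (8,64)
        X = np.array([[0, 4, 0, 4], [0, 8, 0, 8], [0, 16, 0, 16]], dtype=float)
        f = taylor_exponent(X)
        assert f.nu == pytest.approx(2.0)
        assert f.r2 == pytest.approx(1.0)

    def test_exact_slope_from_moments(self):
        # log2 var = nu * log2 mean + c exactly for synthetic moment pairs
        means = np.array([1.0, 2.0, 4.0])
        # two-point series with given mean m and var m (nu=1): m +/- sqrt(m)
        X = np.stack([means - np.sqrt(means), means + np.sqrt(means)], axis=1)
        f = taylor_exponent(X)
        assert f.nu == pytest.approx(1.0)

    def test_zero_variance_rows_excluded_and_counted(self):
        X = np.array([[1, 3], [2, 2], [2, 6], [4, 12]], dtype=float)
        f = taylor_exponent(X)
        assert f.n_points == 3
        assert f.n_excluded == 1

    def test_too_few_points(self):
        with pytest.raises(TooFewPointsError):
            taylor_exponent(np.array([[1, 2], [3, 3]], dtype=float))

    def test_generator_recovery(self, rng):
        # var = mean^1.7 with small log-noise, 200 OTUs
        means = pareto_sample(rng, 200, eps=2.5, xmin=3.0)
        sigma2 = np.log1p(means ** (1.7 - 2.0))
        z = rng.standard_normal((200, 100))
        X = means[:, None] * np.exp(
            np.sqrt(sigma2)[:, None] * z - sigma2[:, None] / 2
        )
        f = taylor_exponent(X)
        assert abs(f.nu - 1.7) <= 0.1


class TestEstimatorAPI:
    def test_powerlaw_estimator_attributes(self, rng):
        est = PowerLawTail(xmin=1.0).fit(pareto_sample(rng, 500, eps=2.5))
        assert est.xmin_ == 1.0
        assert est.exponent_ > 1
        assert est.tail_fit_.family == "powerlaw"

    def test_exponential_estimator_attributes(self, rng):
        est = ExponentialTail(xmin=0.0).fit(rng.exponential(size=500))
        assert est.rate_ > 0

    def test_taylor_estimator_clone_compatible(self, rng):
        from sklearn.base import clone

        est = TaylorLaw()
        clone(est)  # parameters round-trip through get_params/set_params
        X = rng.poisson(10.0, size=(20, 30)).astype(float)
        est.fit(X)
        assert hasattr(est, "nu_")
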