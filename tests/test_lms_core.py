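"""Unit tests of the BCCG distribution primitives and the LMS fitting engine."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from lmsref import FitData, compute_z, exclude_outliers, fit_lms, select_model
from lmsref.lms_core import (
    DomainError,
    bccg_inverse_z,
    bccg_logdensity,
    bccg_z,
)

from conftest import make_constant_model


class TestDensity:
    @pytest.mark.parametrize(
        "L,M,S",
        [(0.5, 10.0, 0.15), (1.0, 5.0, 0.1), (-0.5, 2.0, 0.2), (0.0, 1.0, 0.3), (2.0, 50.0, 0.05)],
    )
    def test_integrates_to_one(self, L, M, S):
        """The BCCG density is a proper density on (0, inf) up to negligible
        truncated mass."""
        val, _ = integrate.quad(
            lambda y: np.exp(bccg_logdensity(y, L, M, S)), 1e-9, 50 * M, limit=300
        )
        assert abs(val - 1.0) < 1e-4

    def test_L1_equals_normal(self):
        """With L = 1 the distribution is normal with mean M and SD M*S."""
        y = np.linspace(5.0, 15.0, 101)
        ours = bccg_logdensity(y, 1.0, 10.0, 0.1)
        ref = stats.norm.logpdf(y, loc=10.0, scale=1.0)
        assert np.max(np.abs(ours - ref)) < 1e-10

    def test_small_L_equals_lognormal(self):
        y = np.linspace(0.5, 5.0, 50)
        ours = bccg_logdensity(y, 1e-9, 2.0, 0.25)
        ref = stats.lognorm.logpdf(y, s=0.25, scale=2.0)
        assert np.max(np.abs(ours - ref)) < 1e-8

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            bccg_logdensity(-1.0, 1.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            bccg_logdensity(1.0, 1.0, -10.0, 0.1)
        with pytest.raises(ValueError):
            bccg_logdensity(1.0, 1.0, 10.0, 0.0)


class TestZTransform:
    def test_median_maps_to_zero(self):
        model = make_constant_model(0.7, 8.0, 0.2)
        assert compute_z(8.0, 40.0, model) == pytest.approx(0.0, abs=1e-12)

    def test_linear_case(self):
        model = make_constant_model(1.0, 10.0, 0.1)
        assert compute_z(12.0, 40.0, model) == pytest.approx(2.0, abs=1e-12)

    def test_lognormal_branch_matches_closed_form(self):
        model = make_constant_model(1e-9, 10.0, 0.2)
        z = compute_z(15.0, 40.0, model)
        assert z == pytest.approx(np.log(1.5) / 0.2, abs=1e-6)

    def test_branches_agree_near_zero_L(self):
        """The generic power branch converges to the lognormal limit."""
        z_exact = bccg_z(15.0, 0.0, 10.0, 0.2)
        z_near = bccg_z(15.0, 2e-5, 10.0, 0.2)
        assert abs(z_near / z_exact - 1.0) < 1e-4

    def test_no_extrapolation(self):
        model = make_constant_model(1.0, 10.0, 0.1)
        with pytest.raises(DomainError):
            compute_z(10.0, 90.0, model)
        with pytest.raises(DomainError):
            compute_z(10.0, 82.0, model)  # domain is half-open

    def test_inverse_round_trip(self):
        z = np.linspace(-3, 3, 21)
        y = bccg_inverse_z(z, 0.4, 7.0, 0.3)
        assert np.max(np.abs(bccg_z(y, 0.4, 7.0, 0.3) - z)) < 1e-10


@pytest.fixture(scope="module")
def iid_data():
    rng = np.random.default_rng(42)
    n = 2000
    t = rng.uniform(18, 82, n)
    z = rng.standard_normal(n)
    y = 10.0 * (1.0 + 0.1 * z)  # L=1, M=10, S=0.1
    return FitData(t, y)


class TestFitting:
    def test_constant_fit_recovers_parameters(self, iid_data):
        m = fit_lms(iid_data, (0, 0, 0))
        assert m.converged
        assert 9.8 <= m.M(50.0) <= 10.2
        assert 0.09 <= m.S(50.0) <= 0.11

    def test_constant_fit_matches_brute_force_mle(self, iid_data):
        """Backfitting with all-constant curves is plain 3-parameter ML."""
        m = fit_lms(iid_data, (0, 0, 0))
        y = iid_data.y

        def negll(p):
            return -np.sum(bccg_logdensity(y, p[0], np.exp(p[1]), np.exp(p[2])))

        res = optimize.minimize(
            negll,
            [1.0, np.log(10.0), np.log(0.1)],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        assert abs(-res.fun - m.log_likelihood) < 1e-3

    def test_fixed_L_matches_normal_likelihood_oracle(self, iid_data):
        """Holding L = 1 reduces the model to normal errors with SD = M*S."""
        m = fit_lms(iid_data, (0, 0, 0), fix_L=1.0)
        y = iid_data.y

        def negll(p):
            mu, s = np.exp(p)
            return -np.sum(stats.norm.logpdf(y, loc=mu, scale=mu * s))

        res = optimize.minimize(
            negll, [np.log(10.0), np.log(0.1)], method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11},
        )
        mu_hat, s_hat = np.exp(res.x)
        assert m.L(50.0) == pytest.approx(1.0)
        assert m.M(50.0) == pytest.approx(mu_hat, rel=1e-4)
        assert m.S(50.0) == pytest.approx(s_hat, rel=1e-3)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_lms(FitData(np.linspace(20, 60, 100), np.full(100, 5.0)), (0, 0, 0))

    def test_minimum_sample_size(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="at least 50"):
            fit_lms(FitData(rng.uniform(20, 60, 30), rng.uniform(5, 10, 30)), (0, 0, 0))

    def test_penalized_loglik_monotone(self):
        """The step-halved backfitting objective never decreases."""
        rng = np.random.default_rng(7)
        n = 1000
        t = rng.uniform(18, 82, n)
        z = rng.standard_normal(n)
        M = 8.0 + 0.05 * (t - 18.0)
        y = M * (1.0 + 0.3 * 0.25 * z) ** (1.0 / 0.3)
        m = fit_lms(FitData(t, y), (0, 3, 1), domain=(18, 82))
        trace = np.asarray(m.penalized_ll_trace)
        assert np.all(np.diff(trace) >= -1e-8 * (np.abs(trace[:-1]) + 1))

    def test_self_simulated_zscores_are_normal(self):
        rng = np.random.default_rng(11)
        n = 5000
        t = rng.uniform(18, 82, n)
        z = rng.standard_normal(n)
        y = 10.0 * np.exp(0.02 * (t - 50) / 10) * (1.0 + 0.15 * z)
        m = fit_lms(FitData(t, y), (0, 2, 1), domain=(18, 82))
        zhat = compute_z(y, t, m)
        assert stats.kstest(zhat, "norm").pvalue > 0.01


class TestSelectModel:
    def test_single_element_grid(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(18, 82, 500)
        y = 5.0 * (1 + 0.1 * rng.standard_normal(500))
        m = select_model(FitData(t, y), [(0, 1, 0)])
        assert m.df == (0, 1, 0)

    def test_bic_penalizes_unneeded_flexibility(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(18, 82, 2000)
        y = 10.0 * (1 + 0.1 * rng.standard_normal(2000))
        m = select_model(FitData(t, y), [(0, 0, 0), (0, 3, 0)])
        assert m.df == (0, 0, 0)

    def test_bic_detects_age_varying_median(self):
        rng = np.random.default_rng(10)
        t = rng.uniform(18, 82, 2000)
        M = 10.0 * (1.0 + (t - 18.0) / 64.0)  # doubles across the domain
        y = M * (1 + 0.1 * rng.standard_normal(2000))
        m = select_model(FitData(t, y), [(0, 0, 0), (0, 3, 0)])
        assert m.df == (0, 3, 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_model(FitData(np.linspace(20, 60, 100), np.linspace(5, 6, 100)), [])


class TestOutlierScreen:
    def test_clean_data_untouched(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(18, 82, 500)
        y = 10.0 + 0.1 * t + rng.standard_normal(500)
        kept, removed = exclude_outliers(FitData(t, y))
        assert removed.size == 0 and len(kept) == 500

    def test_gross_outlier_removed(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(18, 82, 500)
        y = 10.0 + 0.1 * t + rng.standard_normal(500)
        y[123] += 20.0 * np.std(y - (10.0 + 0.1 * t))
        kept, removed = exclude_outliers(FitData(t, y))
        assert list(removed) == [123]
        assert len(kept) == 499

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(18, 82, 100)
        y = rng.uniform(5, 50, 100)
        kept, removed = exclude_outliers(FitData(t, y), threshold=np.inf)
        assert removed.size == 0
        np.testing.assert_array_equal(kept.y, y)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            exclude_outliers(FitData(np.full(50, 40.0), np.linspace(5, 10, 50)))
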