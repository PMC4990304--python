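"""Log-logistic likelihood, MLE, BMD inversion, and profile BMDL."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.stats import chi2

from cadbmd import (FitError, bmd_from_fit, bmdl_profile, fit_loglogistic,
                    goodness_of_fit, loglogistic_prob, quantal_neg_loglik)
from cadbmd.bmd import _profile_nll

DOSES = np.array([0.0, 0.69, 1.20, 1.67, 3.43])


def _simulated_table(g, a, b, n_per_group, rng, doses=DOSES):
    p = loglogistic_prob(doses, g, a, b)
    n = np.full(len(doses), n_per_group)
    return doses, n, rng.binomial(n, p)


class TestProbability:
    def test_dose_zero_is_background(self):
        assert loglogistic_prob(0.0, 0.07, -3.0, 2.0) == pytest.approx(0.07)

    def test_logit_zero_is_half(self):
        assert loglogistic_prob(1.0, 0.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_extra_risk_at_reference_parameters(self):
        # at the dose inverting 10% extra risk the response is g + 0.10(1-g)
        p = loglogistic_prob(2.44, 0.05, -4.02, 2.04)
        assert (p - 0.05) / 0.95 == pytest.approx(0.10, abs=5e-4)
        assert p == pytest.approx(0.145, abs=1e-3)

    def test_monotone_and_saturating(self):
        d = np.linspace(0.01, 100, 500)
        p = loglogistic_prob(d, 0.05, -3.0, 1.5)
        assert (np.diff(p) > 0).all()
        assert loglogistic_prob(1e9, 0.05, -3.0, 1.5) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("g,b", [(-0.1, 1.0), (1.1, 1.0), (0.1, 0.0), (0.1, -2.0)])
    def test_domain_errors(self, g, b):
        with pytest.raises(ValueError):
            loglogistic_prob(1.0, g, 0.0, b)


class TestLikelihood:
    def test_saturated_single_group_closed_form(self):
        # at p = y/n the binomial log-likelihood is y ln p + (n-y) ln(1-p)
        n, y, d = 100.0, 30.0, 1.0
        p = y / n
        a = np.log(p / (1 - p))  # g=0, b=1, dose 1 => P = logistic(a)
        expected = -(y * np.log(p) + (n - y) * np.log(1 - p))
        assert quantal_neg_loglik((0.0, a, 1.0), [d], [n], [y]) == pytest.approx(expected)

    def test_perfect_fit_limit(self):
        # no positives anywhere and a vanishing response: likelihood -> 1
        val = quantal_neg_loglik((1e-12, -30.0, 5.0), DOSES, [50] * 5, [0] * 5)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_probability_is_finite(self):
        # P ~ 0 with positives observed: barrier value, not a crash
        val = quantal_neg_loglik((1e-12, -50.0, 1.0), DOSES, [50] * 5, [5] * 5)
        assert np.isfinite(val)


class TestFit:
    def test_parameter_recovery_large_groups(self, rng):
        g, a, b = 0.06, -3.5, 1.8
        d, n, y = _simulated_table(g, a, b, 10_000, rng)
        fit = fit_loglogistic((d, n, y))
        assert fit.g == pytest.approx(g, rel=0.05)
        assert fit.a == pytest.approx(a, rel=0.05)
        assert fit.b == pytest.approx(b, rel=0.05)

    def test_matches_grid_polish_oracle(self, all_study_tables_90):
        # independent brute-force optimum: coarse lattice + Nelder-Mead polish
        for t in all_study_tables_90:
            d = np.array(t.doses)
            n = np.array(t.n, float)
            y = np.array(t.positives, float)
            best = np.inf
            for g0 in (0.02, 0.06, 0.10):
                for a0 in (-6.0, -3.5, -1.5):
                    for b0 in (1.0, 1.7, 3.0):
                        res = minimize(
                            lambda p: quantal_neg_loglik(
                                (min(max(p[0], 1e-9), 1 - 1e-9), p[1], max(p[2], 1.0)),
                                d, n, y),
                            [g0, a0, b0], method="Nelder-Mead",
                            options=dict(xatol=1e-9, fatol=1e-11, maxiter=5000))
                        best = min(best, res.fun)
            fit = fit_loglogistic(t)
            assert fit.negloglik == pytest.approx(best, abs=1e-3)

    def test_slope_restriction_bound(self):
        # a shallow table pushes the slope to the b >= 1 bound when restricted
        d = DOSES
        n = np.array([164, 133, 68, 26, 38])
        y = np.array([9, 11, 13, 4, 6])
        restricted = fit_loglogistic((d, n, y), restrict_slope=True)
        assert restricted.slope_at_bound and restricted.b == pytest.approx(1.0)
        assert restricted.n_params == 2  # pinned slope not counted
        free = fit_loglogistic((d, n, y), restrict_slope=False)
        assert free.b < 1.0
        assert free.loglik >= restricted.loglik

    def test_fixed_parameter_count_option(self):
        d, n, y = DOSES, [164, 133, 68, 26, 38], [9, 11, 13, 4, 6]
        fit = fit_loglogistic((d, n, y), count_boundary_params=True)
        assert fit.n_params == 3
        assert fit.aic == pytest.approx(6.0 - 2.0 * fit.loglik)

    def test_aic_identity(self, male_rbp_table):
        fit = fit_loglogistic(male_rbp_table)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(FitError):
            fit_loglogistic(([0.0, 1.0], [10, 10], [1, 2]))  # too few groups
        with pytest.raises(FitError):
            fit_loglogistic((DOSES, [10] * 5, [0] * 5))  # no positives


class TestBMD:
    @pytest.mark.parametrize("a,b,bmr,expected,tol", [
        (-4.02, 2.04, 0.10, 2.4437, 1e-3),
        (-2.80, 1.00, 0.10, 1.8272, 1e-3),
        (np.log(1 / 9), 1.0, 0.10, 1.0, 1e-12),  # unit dose by construction
    ])
    def test_closed_form_inversion(self, a, b, bmr, expected, tol):
        assert bmd_from_fit((a, b), bmr) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bmr", [0.0, 1.0, -0.1, 1.5])
    def test_bmr_domain(self, bmr):
        with pytest.raises(ValueError):
            bmd_from_fit((-3.0, 1.5), bmr)

    def test_monotone_in_bmr(self, male_rbp_table):
        fit = fit_loglogistic(male_rbp_table)
        assert bmd_from_fit(fit, 0.05) < bmd_from_fit(fit, 0.10)

    @given(g=st.floats(0.0, 0.5), a=st.floats(-8.0, 2.0),
           b=st.floats(0.5, 5.0), bmr=st.floats(0.01, 0.4))
    @settings(max_examples=200, deadline=None)
    def test_extra_risk_roundtrip(self, g, a, b, bmr):
        # (P(BMD) - g)/(1 - g) == bmr identically, independent of g
        d = bmd_from_fit((a, b), bmr)
        p = loglogistic_prob(d, g, a, b)
        assert (p - g) / (1.0 - g) == pytest.approx(bmr, abs=1e-10)


class TestBMDL:
    def test_lower_than_bmd_on_study_fits(self, all_study_tables_90):
        for t in all_study_tables_90:
            fit = fit_loglogistic(t)
            for bmr in (0.05, 0.10):
                assert bmdl_profile(fit, t, bmr) < bmd_from_fit(fit, bmr)

    def test_agrees_with_dense_grid_oracle(self, rng):
        d, n, y = _simulated_table(0.06, -3.5, 1.8, 150, rng)
        fit = fit_loglogistic((d, n, y))
        bmdl = bmdl_profile(fit, (d, n, y), 0.10)
        crit = fit.negloglik + chi2.ppf(0.90, 1) / 2
        grid = np.linspace(0.5 * bmdl, bmd_from_fit(fit, 0.10), 400)
        prof = np.array([_profile_nll(D, 0.10, d.astype(float), n.astype(float),
                                      y.astype(float), 1.0, None) for D in grid])
        oracle = grid[np.argmax(prof < crit)]  # first dose inside the region
        assert bmdl == pytest.approx(oracle, abs=grid[1] - grid[0])

    def test_profile_height_at_limit(self, male_rbp_table):
        # at the BMDL the profiled likelihood sits exactly on the cut
        fit = fit_loglogistic(male_rbp_table)
        bmdl = bmdl_profile(fit, male_rbp_table, 0.10)
        d = np.array(male_rbp_table.doses)
        n = np.array(male_rbp_table.n, float)
        y = np.array(male_rbp_table.positives, float)
        h = _profile_nll(bmdl, 0.10, d, n, y, 1.0, None)
        assert h - fit.negloglik == pytest.approx(chi2.ppf(0.90, 1) / 2, abs=1e-5)

    def test_tighter_at_higher_confidence(self, male_rbp_table):
        fit = fit_loglogistic(male_rbp_table)
        l95 = bmdl_profile(fit, male_rbp_table, 0.10, confidence=0.95)
        l99 = bmdl_profile(fit, male_rbp_table, 0.10, confidence=0.99)
        assert l99 < l95


class TestGoodnessOfFit:
    def test_near_perfect_fit(self, rng):
        d, n, y = _simulated_table(0.05, -3.0, 1.5, 100_000, rng)
        fit = fit_loglogistic((d, n, y))
        assert goodness_of_fit(fit) > 0.5

    def test_misspecified_model_rejected(self):
        # non-monotone response cannot be explained by any monotone fit
        d = DOSES
        n = np.array([2000] * 5)
        y = np.array([100, 800, 100, 800, 100])
        fit = fit_loglogistic((d, n, y))
        assert goodness_of_fit(fit) < 0.05

    def test_undefined_when_no_degrees_of_freedom(self, rng):
        d = np.array([0.0, 1.0, 2.0])
        n = np.array([200, 200, 200])
        y = np.array([10, 30, 80])
        fit = fit_loglogistic((d, n, y))  # 3 groups, 3 parameters
        if fit.n_params == 3:
            assert np.isnan(fit.gof_p)
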