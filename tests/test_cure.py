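"""Mixture cure model: E/M steps, EM ascent, recovery, reductions, inference."""

import numpy as np
import pytest

from curescan.cure import (
    CureModelSpec,
    CureParams,
    cure_se,
    e_step,
    fit_mixture_cure,
    m_step,
    observed_loglik,
    susceptible_survival,
)
from curescan.exceptions import DegenerateWeightsError, NoEventsError
from curescan.simulate import CohortSpec, SnpEffect, simulate_cohort
from curescan.survival import cox_fit


def binary_spec(x, latency_form="semiparametric"):
    Z = np.column_stack([np.ones(len(x)), x])
    return CureModelSpec(Z, x, latency_form=latency_form)


def toy_params(event_times, hazard, b, beta):
    return CureParams(
        incidence_coefs=np.asarray(b, float),
        latency_coefs=np.asarray(beta, float),
        event_times=np.asarray(event_times, float),
        baseline_hazard=np.asarray(hazard, float),
    )


class TestESteps:
    @staticmethod
    def intercept_spec(n):
        return CureModelSpec(np.ones((n, 1)), np.zeros((n, 1)))

    def test_event_subject_weight_one(self):
        params = toy_params([1.0], [0.2], [0.0], [0.0])
        w = e_step(params, [1.0, 0.5, 2.0], [1, 0, 0], self.intercept_spec(3))
        assert w[0] == 1.0

    def test_censored_beyond_last_event_weight_zero(self):
        # zero tail: S_u = 0 past the largest event time
        params = toy_params([1.0], [0.2], [0.0], [0.0])
        w = e_step(params, [1.0, 5.0], [1, 0], self.intercept_spec(2))
        assert w[1] == 0.0

    def test_half_pi_half_survival_gives_third(self):
        # pi = 0.5, S_u(t) = 0.5 -> w = 0.25 / 0.75 = 1/3
        lam = -np.log(0.5)  # cumulative hazard giving S0 = 0.5
        params = toy_params([2.0], [lam], [0.0], [0.0])
        w = e_step(params, [2.0], [0], self.intercept_spec(1))
        assert w[0] == pytest.approx(1 / 3)

    def test_zero_tail_in_susceptible_survival(self):
        params = toy_params([1.0, 2.0], [0.1, 0.2], [0.0], [0.0])
        su = susceptible_survival(params, np.array([0.5, 2.0, 2.01]), np.zeros((3, 1)))
        assert su[0] == pytest.approx(1.0)
        assert su[1] == pytest.approx(np.exp(-0.3))
        assert su[2] == 0.0


class TestMStep:
    def test_unit_weights_reduce_to_cox(self, default_cohort):
        c = default_cohort
        x = (c.genotypes.codes[0] >= 1).astype(float)
        spec = binary_spec(x)
        params = m_step(np.ones(c.spec.n), c.times, c.events, spec)
        ref = cox_fit(c.times, c.events, x)
        assert params.latency_coefs[0] == pytest.approx(ref.coefficients[0], abs=1e-6)

    def test_unit_weights_cap_incidence_intercept(self):
        # all-susceptible weights force the logistic intercept to +inf: capped
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 50)
        e = np.ones(50, int)
        spec = CureModelSpec(np.ones((50, 1)), rng.normal(size=(50, 1)))
        with pytest.warns(UserWarning, match="capped"):
            params = m_step(np.ones(50), t, e, spec)
        assert params.incidence_coefs[0] == pytest.approx(15.0)

    def test_fixed_point_of_converged_fit(self, default_cohort):
        c = default_cohort
        x = c.genotypes.codes[0].astype(float)
        spec = binary_spec(x)
        fit = fit_mixture_cure(c.times, c.events, spec, se_method="none")
        assert fit.converged
        w = e_step(fit.params, c.times, c.events, spec)
        params2 = m_step(w, c.times, c.events, spec, init=fit.params)
        ll2 = observed_loglik(params2, c.times, c.events, spec)
        assert abs(ll2 - fit.observed_loglik) < 1e-4

    def test_matches_grid_maximization_of_weighted_objective(self):
        """Latency update equals brute-force maximization of the weighted
        partial likelihood, written here as naive risk-set loops."""
        rng = np.random.default_rng(5)
        n = 60
        t = rng.exponential(1, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        x = rng.normal(size=n)
        w = np.where(e == 1, 1.0, rng.random(n))
        spec = binary_spec(x)
        params = m_step(w, t, e, spec)

        def naive_weighted_pll(beta):
            ll = 0.0
            for i in range(n):
                if e[i] == 1:
                    risk = t >= t[i]
                    ll += beta * x[i] - np.log(np.sum(w[risk] * np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-2, 2, 4001)
        best = grid[np.argmax([naive_weighted_pll(b) for b in grid])]
        assert params.latency_coefs[0] == pytest.approx(best, abs=2e-3)

    def test_degenerate_weights_error(self):
        spec = binary_spec(np.zeros(3))
        with pytest.raises(DegenerateWeightsError):
            m_step(np.zeros(3), [1, 2, 3], [1, 1, 0], spec)


class TestObservedLoglik:
    def test_direct_summation_five_patients(self):
        times = np.array([1.0, 2.0, 3.0, 2.5, 4.0])
        events = np.array([1, 1, 1, 0, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        b = np.array([-0.5, 0.8])
        beta = np.array([0.6])
        ev_t = np.array([1.0, 2.0, 3.0])
        haz = np.array([0.2, 0.3, 0.5])
        spec = binary_spec(x)
        params = toy_params(ev_t, haz, b, beta)
        # independent summation, term by term
        pi = 1 / (1 + np.exp(-(b[0] + b[1] * x)))
        cum = np.cumsum(haz)
        expected = 0.0
        for i in range(5):
            rr = np.exp(beta[0] * x[i])
            if events[i] == 1:
                j = list(ev_t).index(times[i])
                su = np.exp(-cum[j] * rr)
                expected += np.log(pi[i] * haz[j] * rr * su)
            else:
                lam = cum[np.searchsorted(ev_t, times[i], side="right") - 1] if times[i] >= ev_t[0] else 0.0
                su = 0.0 if times[i] > ev_t[-1] else np.exp(-lam * rr)
                expected += np.log(1 - pi[i] + pi[i] * su)
        assert observed_loglik(params, times, events, spec) == pytest.approx(expected)

    def test_em_ascent_and_nesting(self, default_cohort):
        c = default_cohort
        x = c.genotypes.codes[0].astype(float)
        fit = fit_mixture_cure(c.times, c.events, binary_spec(x), se_method="none")
        hist = np.asarray(fit.loglik_history)
        assert np.all(np.diff(hist) >= -1e-8 * (1 + np.abs(hist[:-1])))
        # adding a covariate never decreases the maximized value
        null_spec = CureModelSpec(np.ones((c.spec.n, 1)), np.zeros((c.spec.n, 0)))
        null_fit = fit_mixture_cure(c.times, c.events, null_spec, se_method="none")
        assert fit.observed_loglik >= null_fit.observed_loglik - 1e-6


class TestFitMixtureCure:
    def test_no_events_errors(self):
        spec = binary_spec(np.zeros(4))
        with pytest.raises(NoEventsError):
            fit_mixture_cure([1, 2, 3, 4], [0, 0, 0, 0], spec)

    def test_identifiability_warning_without_late_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 40)
        e = np.ones(40, int)
        e[t < np.median(t)] = 1
        # make the largest time an event: no censored subject at/after it
        spec = binary_spec(rng.normal(size=40))
        fit = fit_mixture_cure(t, e, spec, se_method="none")
        assert fit.identifiability_warning

    def test_all_susceptible_data_latency_matches_cox(self):
        # heavy-event data: cure fraction ~ 0, latency ~ plain Cox within 2 SE
        rng = np.random.default_rng(2)
        n = 800
        x = rng.integers(0, 2, n).astype(float)
        t0 = rng.exponential(1 / np.exp(0.8 * x))
        cmax = np.quantile(t0, 0.97)
        t = np.minimum(t0, cmax)
        e = (t0 <= cmax).astype(int)
        fit = fit_mixture_cure(t, e, binary_spec(x), se_method="none")
        ref = cox_fit(t, e, x)
        assert abs(fit.params.latency_coefs[0] - ref.coefficients[0]) < 2 * ref.se[0]

    def test_cure_fraction_recovery_at_study_scale(self):
        # intercept-only incidence, null latency, true cure fraction 0.71
        ests = []
        for s in range(40):
            c = simulate_cohort(CohortSpec(n=379, seed=1000 + s))
            spec = CureModelSpec(np.ones((379, 1)), np.zeros((379, 0)))
            fit = fit_mixture_cure(c.times, c.events, spec, se_method="none")
            pi = 1 / (1 + np.exp(-fit.params.incidence_coefs[0]))
            ests.append(1 - pi)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.71) < 3 * mc_se + 0.01

    def test_weibull_latency_cross_check(self, effect_cohort):
        c = effect_cohort
        x = (c.genotypes.codes[0] >= 1).astype(float)
        semi = fit_mixture_cure(c.times, c.events, binary_spec(x), se_method="none")
        para = fit_mixture_cure(
            c.times, c.events, binary_spec(x, "weibull"), se_method="none"
        )
        # the two latency formulations agree on the data-generating truth
        assert abs(semi.params.latency_coefs[0] - para.params.latency_coefs[0]) < 0.25
        assert abs(para.params.weibull_shape - 1.2) < 0.3


class TestCureSe:
    @pytest.fixture(scope="class")
    def small_fit(self):
        c = simulate_cohort(
            CohortSpec(
                n=150,
                maf_list=(0.35,),
                seed=42,
                snp_effects=(SnpEffect(0, "dominant", 0.6, 0.7),),
            )
        )
        x = (c.genotypes.codes[0] >= 1).astype(float)
        spec = binary_spec(x)
        fit = fit_mixture_cure(c.times, c.events, spec, se_method="none")
        return fit, c.times, c.events

    def test_bootstrap_deterministic_for_seed(self, small_fit):
        fit, t, e = small_fit
        a = cure_se(fit, t, e, n_boot=40, seed=7)
        ci_a = (a.incidence_ci.copy(), a.latency_ci.copy())
        b = cure_se(fit, t, e, n_boot=40, seed=7)
        assert np.array_equal(ci_a[0], b.incidence_ci)
        assert np.array_equal(ci_a[1], b.latency_ci)

    def test_doubling_n_boot_stable(self, small_fit):
        fit, t, e = small_fit
        a = cure_se(fit, t, e, n_boot=60, seed=1)
        w_a = a.latency_ci[0, 1] - a.latency_ci[0, 0]
        b = cure_se(fit, t, e, n_boot=120, seed=2)
        w_b = b.latency_ci[0, 1] - b.latency_ci[0, 0]
        # CI endpoints are Monte-Carlo stable: same order of magnitude
        assert 0.4 < w_b / w_a < 2.5

    def test_null_effect_coverage(self):
        """Bootstrap 95% CI covers the true zero coefficient at roughly the
        nominal rate (reduced n_boot for speed; wide Monte-Carlo band)."""
        cover = 0
        n_rep = 60
        for s in range(n_rep):
            c = simulate_cohort(CohortSpec(n=120, maf_list=(0.4,), seed=3000 + s))
            x = (c.genotypes.codes[0] >= 1).astype(float)
            fit = fit_mixture_cure(
                c.times, c.events, binary_spec(x),
                se_method="bootstrap", n_boot=60, seed=s,
            )
            lo, hi = fit.latency_ci[1 - 1]  # single latency coefficient
            cover += lo <= 1.0 <= hi  # OR/HR scale: null = 1
        assert 0.85 <= cover / n_rep <= 1.0
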