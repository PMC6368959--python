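"""Semiparametric mixture cure model fitted by EM.

The population is modelled as a mixture of cured (never metastasizing)
patients and susceptible patients:

    S_pop(t | z, x) = 1 - pi(z) + pi(z) * S_u(t | x)

where pi(z) = expit(b'z) is the probability of being susceptible (the
*incidence* component, a logistic regression reported as odds ratios) and
S_u(t | x) is proportional-hazards survival among the susceptible (the
*latency* component, reported as hazard ratios). The default latency is
semiparametric: Cox partial likelihood with a weighted Breslow baseline and
the zero-tail constraint (S_u = 0 beyond the largest event time), which makes
the cured fraction identifiable. A parametric Weibull latency is available
for cross-checking.

The EM alternates:

* E-step — posterior susceptibility weights: w_i = 1 for events, and
  w_i = pi_i S_u(t_i) / (1 - pi_i + pi_i S_u(t_i)) for censored subjects;
* M-step — logistic regression of w on z (fractional responses) and a
  case-weighted Cox fit of the latency (subjects enter risk sets with weight
  w_i; w_i = 0 leaves the risk set), followed by a weighted Breslow baseline
  update with the zero tail re-imposed.

The observed-data log-likelihood is monitored every iteration and is
non-decreasing up to numerical tolerance (EM ascent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from ._engines import COEF_CAP, _loglik_grad_hess, cox_newton, logistic_irls
from .exceptions import (
    DegenerateWeightsError,
    NoEventsError,
    UndefinedInputError,
)

_Z975 = 1.959963984540054


@dataclass
class CureModelSpec:
    """Designs for the two components; incidence must carry an intercept."""

    incidence_design: np.ndarray  # n x q, first column all ones
    latency_design: np.ndarray  # n x p
    incidence_names: list = None
    latency_names: list = None
    latency_form: str = "semiparametric"  # or "weibull"

    def __post_init__(self):
        self.incidence_design = np.atleast_2d(np.asarray(self.incidence_design, float))
        self.latency_design = np.asarray(self.latency_design, float)
        if self.latency_design.ndim == 1:
            self.latency_design = self.latency_design[:, None]
        if self.incidence_design.ndim == 1:
            self.incidence_design = self.incidence_design[:, None]
        if self.incidence_design.shape[0] != self.latency_design.shape[0]:
            raise UndefinedInputError("incidence and latency designs cover different patients")
        if not np.allclose(self.incidence_design[:, 0], 1.0):
            raise UndefinedInputError("incidence design must have an intercept first column")
        if self.incidence_names is None:
            self.incidence_names = ["intercept"] + [
                f"z{i}" for i in range(1, self.incidence_design.shape[1])
            ]
        if self.latency_names is None:
            self.latency_names = [f"x{i}" for i in range(self.latency_design.shape[1])]
        if self.latency_form not in ("semiparametric", "weibull"):
            raise ValueError(f"unknown latency form {self.latency_form!r}")

    @property
    def n(self) -> int:
        return self.incidence_design.shape[0]


@dataclass
class CureParams:
    """Parameter state of the mixture cure model during / after EM."""

    incidence_coefs: np.ndarray  # b, log-odds of susceptibility
    latency_coefs: np.ndarray  # beta, log-hazards among susceptibles
    event_times: np.ndarray  # distinct event times
    baseline_hazard: np.ndarray  # Breslow increments at event_times
    latency_form: str = "semiparametric"
    weibull_shape: float = np.nan
    weibull_scale: float = np.nan


@dataclass
class CureModelFit:
    """Fitted mixture cure model with Table-style OR / HR summaries."""

    spec: CureModelSpec
    params: CureParams
    weights: np.ndarray  # final E-step susceptibility weights
    observed_loglik: float
    loglik_history: np.ndarray
    em_iterations: int
    converged: bool
    incidence_separation: bool
    identifiability_warning: bool
    n: int
    n_events: int
    # inference, attached by cure_se (NaN until then)
    incidence_se: np.ndarray = None
    latency_se: np.ndarray = None
    incidence_ci: np.ndarray = None  # q x 2 on the OR scale
    latency_ci: np.ndarray = None  # p x 2 on the HR scale
    incidence_p: np.ndarray = None
    latency_p: np.ndarray = None
    se_method: str = "none"
    n_boot_requested: int = 0
    n_boot_converged: int = 0

    @property
    def incidence_or(self) -> np.ndarray:
        return np.exp(self.params.incidence_coefs)

    @property
    def latency_hr(self) -> np.ndarray:
        return np.exp(self.params.latency_coefs)

    def susceptibility(self) -> np.ndarray:
        """pi(z) per patient under the fitted incidence component."""
        eta = np.clip(self.spec.incidence_design @ self.params.incidence_coefs, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))

    def baseline_survival(self) -> tuple[np.ndarray, np.ndarray]:
        """(event times, S_0 at those times); zero beyond the last event."""
        if self.params.latency_form == "weibull":
            t = self.params.event_times
            s0 = np.exp(-((t / self.params.weibull_scale) ** self.params.weibull_shape))
            return t, s0
        return self.params.event_times, np.exp(-np.cumsum(self.params.baseline_hazard))


def susceptible_survival(params: CureParams, times, latency_design) -> np.ndarray:
    """S_u(t_i | x_i) per subject, with the zero-tail constraint applied."""
    times = np.asarray(times, float)
    X = np.asarray(latency_design, float)
    if X.ndim == 1:
        X = X[:, None]
    rr = np.exp(np.clip(X @ params.latency_coefs, -COEF_CAP * 4, COEF_CAP * 4))
    if params.latency_form == "weibull":
        cumhaz = (times / params.weibull_scale) ** params.weibull_shape
        return np.exp(-cumhaz * rr)
    if params.event_times.size == 0:
        raise NoEventsError("no event times in baseline")
    cum = np.concatenate([[0.0], np.cumsum(params.baseline_hazard)])
    lam0 = cum[np.searchsorted(params.event_times, times, side="right")]
    su = np.exp(-lam0 * rr)
    su[times > params.event_times[-1]] = 0.0  # zero tail
    return su


def e_step(params: CureParams, times, events, spec: CureModelSpec) -> np.ndarray:
    """Posterior probability of being susceptible; exactly 1 for events."""
    events = np.asarray(events, int)
    eta = np.clip(spec.incidence_design @ params.incidence_coefs, -30, 30)
    pi = 1.0 / (1.0 + np.exp(-eta))
    su = susceptible_survival(params, times, spec.latency_design)
    if not (np.isfinite(pi).all() and np.isfinite(su).all()):
        raise UndefinedInputError(
            f"non-finite E-step intermediates: b={params.incidence_coefs}, "
            f"beta={params.latency_coefs}"
        )
    num = pi * su
    denom = 1.0 - pi + num
    w = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    w = np.where(events == 1, 1.0, w)
    return w


def _weibull_mstep(weights, times, events, X, init):
    """Weighted complete-data Weibull PH maximization over (log k, log lam, beta)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    w = np.asarray(weights, float)
    logt = np.log(t)
    ev = e == 1

    def negll(theta):
        k = np.exp(theta[0])
        lam = np.exp(theta[1])
        beta = theta[2:]
        eta = np.clip(X @ beta, -60, 60)
        cumh = (t / lam) ** k * np.exp(eta)
        ll = np.sum(np.log(k) - np.log(lam) + (k - 1) * (logt[ev] - np.log(lam)) + eta[ev]) if ev.any() else 0.0
        ll -= np.sum(w * cumh)
        return -ll

    res = optimize.minimize(negll, init, method="Nelder-Mead" if len(init) <= 3 else "BFGS")
    res = optimize.minimize(negll, res.x, method="BFGS")
    return res.x


def m_step(
    weights,
    times,
    events,
    spec: CureModelSpec,
    init: CureParams = None,
    newton_iter: int = 100,
) -> CureParams:
    """Maximize the weighted complete-data likelihood given susceptibility weights.

    Incidence: logistic IRLS of the fractional weights on z (|b| capped at
    15 under separation). Latency: case-weighted Cox partial likelihood —
    equivalent to entering log w as a fixed offset, subjects with w = 0 leave
    the risk set — then a weighted Breslow baseline with the zero tail.
    """
    w = np.asarray(weights, float)
    events = np.asarray(events, int)
    if not ((w >= 0) & (w <= 1 + 1e-12)).all():
        raise DegenerateWeightsError("weights outside [0, 1]")
    if w.sum() <= 0:
        raise DegenerateWeightsError("all susceptibility weights are zero")
    if events.sum() == 0:
        raise NoEventsError("M-step requires at least one event")

    b, _, _, capped = logistic_irls(
        spec.incidence_design, w, init=None if init is None else init.incidence_coefs
    )
    if capped:
        warnings.warn("incidence separation: coefficient capped at |b| = 15", stacklevel=2)

    if spec.latency_form == "weibull":
        p = spec.latency_design.shape[1]
        theta0 = (
            np.concatenate([[0.0, np.log(np.median(times))], np.zeros(p)])
            if init is None or not np.isfinite(init.weibull_shape)
            else np.concatenate(
                [[np.log(init.weibull_shape), np.log(init.weibull_scale)], init.latency_coefs]
            )
        )
        theta = _weibull_mstep(w, times, events, spec.latency_design, theta0)
        ev_t = np.unique(np.asarray(times, float)[events == 1])
        return CureParams(
            incidence_coefs=b,
            latency_coefs=theta[2:],
            event_times=ev_t,
            baseline_hazard=np.empty(0),
            latency_form="weibull",
            weibull_shape=float(np.exp(theta[0])),
            weibull_scale=float(np.exp(theta[1])),
        )

    # Breslow ties: the exact profile of the complete-data objective whose
    # baseline update is the weighted Breslow estimator (EM ascent requires
    # the two to match; with untied event times Efron coincides anyway)
    res = cox_newton(
        times,
        events,
        spec.latency_design,
        weights=w,
        ties="breslow",
        init=None if init is None else init.latency_coefs,
        max_iter=newton_iter,
        compute_null=False,
    )
    return CureParams(
        incidence_coefs=b,
        latency_coefs=res.beta,
        event_times=res.event_times,
        baseline_hazard=res.baseline_hazard,
        latency_form="semiparametric",
    )


def observed_loglik(params: CureParams, times, events, spec: CureModelSpec) -> float:
    """Observed-data log-likelihood under the fitted discrete baseline hazard.

    Events contribute log(pi h_u S_u); censored subjects log(1 - pi + pi S_u).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    eta = np.clip(spec.incidence_design @ params.incidence_coefs, -30, 30)
    pi = 1.0 / (1.0 + np.exp(-eta))
    su = susceptible_survival(params, times, spec.latency_design)
    xb = np.clip(spec.latency_design @ params.latency_coefs, -COEF_CAP * 4, COEF_CAP * 4)
    ev = events == 1

    if params.latency_form == "weibull":
        k, lam = params.weibull_shape, params.weibull_scale
        log_h0 = np.log(k) - np.log(lam) + (k - 1) * (np.log(times[ev]) - np.log(lam))
    else:
        idx = np.searchsorted(params.event_times, times[ev])
        if not np.all(
            (idx < params.event_times.size) & (params.event_times[idx] == times[ev])
        ):
            raise UndefinedInputError("event time absent from baseline hazard support")
        log_h0 = np.log(params.baseline_hazard[idx])

    ll_event = np.log(pi[ev]) + log_h0 + xb[ev] + np.log(np.maximum(su[ev], 1e-300))
    ll_cens = np.log(np.maximum(1.0 - pi[~ev] + pi[~ev] * su[~ev], 1e-300))
    total = float(ll_event.sum() + ll_cens.sum())
    if not np.isfinite(total):
        raise UndefinedInputError("non-finite observed log-likelihood")
    return total


def _em_semiparametric(times, events, spec, max_iter, tol, init_params):
    """EM inner loop for the semiparametric latency, on presorted data.

    Numerically identical to alternating :func:`e_step` / :func:`m_step`
    (asserted in the test suite) but presorts once and reuses the fixed tie
    structure, which matters when the scan runs thousands of fits.
    Returns (params, final weights in original order, loglik history, n_iter,
    converged).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    Zs = spec.incidence_design[order]
    Xs = spec.latency_design[order]
    n, p = Xs.shape
    ev = es == 1
    d_idx = np.flatnonzero(ev)
    unique_d, d_start, d_count = np.unique(ts[d_idx], return_index=True, return_counts=True)
    first = np.searchsorted(ts, unique_d, side="left")
    pos = np.searchsorted(unique_d, ts, side="right")
    tail = ts > unique_d[-1]
    ev_pos = np.searchsorted(unique_d, ts[ev])
    d_wsum = d_count.astype(float)  # event weights are always 1

    def baseline(beta, w):
        r = w * np.exp(np.clip(Xs @ beta, -60, 60))
        s0 = np.cumsum(r[::-1])[::-1]
        return d_wsum / s0[first]

    def survival_all(beta, haz):
        cum = np.concatenate([[0.0], np.cumsum(haz)])
        rr = np.exp(np.clip(Xs @ beta, -60, 60))
        su = np.exp(-cum[pos] * rr)
        su[tail] = 0.0
        return su

    def obs_ll(b, beta, haz, pi, su):
        xb = np.clip(Xs @ beta, -60, 60)
        ll_ev = np.log(pi[ev]) + np.log(haz[ev_pos]) + xb[ev] + np.log(
            np.maximum(su[ev], 1e-300)
        )
        ll_ce = np.log(np.maximum(1.0 - pi[~ev] + pi[~ev] * su[~ev], 1e-300))
        return float(ll_ev.sum() + ll_ce.sum())

    def expit_clip(eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    # initial state
    if init_params is not None and init_params.event_times.size == unique_d.size:
        b = init_params.incidence_coefs.copy()
        beta = init_params.latency_coefs.copy()
        haz = init_params.baseline_hazard.copy()
    else:
        w0 = np.where(ev, 1.0, 0.5)
        b, _, _, _ = logistic_irls(Zs, w0)
        res = cox_newton(ts, es, Xs, weights=w0, compute_null=False)
        beta, haz = res.beta, res.baseline_hazard
    pi = expit_clip(Zs @ b)
    su = survival_all(beta, haz)
    ll = obs_ll(b, beta, haz, pi, su)
    history = [ll]
    converged = False
    it = 0
    w = np.where(ev, 1.0, pi * su / np.maximum(1.0 - pi + pi * su, 1e-300))
    for it in range(1, max_iter + 1):
        # E-step
        num = pi * su
        denom = 1.0 - pi + num
        w = np.where(ev, 1.0, num / np.maximum(denom, 1e-300))
        # M-step: logistic IRLS + one damped Newton step on the weighted
        # partial likelihood (ECM), then the Breslow baseline update
        b, _, _, _ = logistic_irls(Zs, w, init=b)
        if p:
            pll, grad, hess = _loglik_grad_hess(beta, ts, es, Xs, w, np.zeros(n), "breslow")
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            new_beta = beta + step
            new_pll = _loglik_grad_hess(new_beta, ts, es, Xs, w, np.zeros(n), "breslow")[0]
            halvings = 0
            while (not np.isfinite(new_pll) or new_pll < pll - 1e-12) and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new_pll = _loglik_grad_hess(new_beta, ts, es, Xs, w, np.zeros(n), "breslow")[0]
                halvings += 1
            beta = new_beta
        haz = baseline(beta, w)
        pi = expit_clip(Zs @ b)
        su = survival_all(beta, haz)
        new_ll = obs_ll(b, beta, haz, pi, su)
        history.append(new_ll)
        if new_ll < ll - 1e-8 * (1.0 + abs(ll)):
            break
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    params = CureParams(
        incidence_coefs=b,
        latency_coefs=beta,
        event_times=unique_d,
        baseline_hazard=haz,
        latency_form="semiparametric",
    )
    # final weights back in input order
    num = pi * su
    w_sorted = np.where(ev, 1.0, num / np.maximum(1.0 - pi + num, 1e-300))
    w_out = np.empty(n)
    w_out[order] = w_sorted
    return params, w_out, np.asarray(history), it, converged


def fit_mixture_cure(
    times,
    events,
    spec: CureModelSpec,
    max_iter: int = 500,
    tol: float = 1e-6,
    se_method: str = "bootstrap",
    n_boot: int = 200,
    seed: int = None,
    init_params: CureParams = None,
) -> CureModelFit:
    """Fit the mixture cure model by EM.

    ``se_method`` is "bootstrap" (percentile CIs, default), "numeric-hessian"
    (Wald from the observed-likelihood Hessian; intended for the Weibull
    latency), or "none" (point estimates only — the scan attaches
    likelihood-ratio p-values instead).

    Non-convergence within ``max_iter`` is recorded on the fit, not raised.
    A cohort with no censored subject at or beyond the last event time leaves
    the cure fraction unidentified; the fit then carries
    ``identifiability_warning``.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        raise NoEventsError("mixture cure model requires at least one event")

    last_event = times[events == 1].max()
    ident_warn = not np.any((events == 0) & (times >= last_event))

    if spec.latency_form == "semiparametric":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, w, history, it, converged = _em_semiparametric(
                times, events, spec, max_iter, tol, init_params
            )
        history = list(history)
    else:
        # generic EM for the parametric (Weibull) latency
        if init_params is not None:
            w = e_step(init_params, times, events, spec)
            params = m_step(w, times, events, spec, init=init_params)
        else:
            w = np.where(events == 1, 1.0, 0.5)
            params = m_step(w, times, events, spec)
        ll = observed_loglik(params, times, events, spec)
        history = [ll]
        converged = False
        it = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for it in range(1, max_iter + 1):
                w = e_step(params, times, events, spec)
                params = m_step(w, times, events, spec, init=params)
                new_ll = observed_loglik(params, times, events, spec)
                history.append(new_ll)
                if new_ll < ll - 1e-8 * (1.0 + abs(ll)):
                    # EM ascent violated beyond numerical noise: stop defensively
                    break
                if abs(new_ll - ll) < tol:
                    ll = new_ll
                    converged = True
                    break
                ll = new_ll
        w = e_step(params, times, events, spec)
    ll = history[-1]
    sep = bool(np.abs(params.incidence_coefs).max() >= COEF_CAP - 1e-9)

    fit = CureModelFit(
        spec=spec,
        params=params,
        weights=w,
        observed_loglik=ll,
        loglik_history=np.asarray(history),
        em_iterations=it,
        converged=converged,
        incidence_separation=sep,
        identifiability_warning=ident_warn,
        n=len(times),
        n_events=int(events.sum()),
    )
    q = spec.incidence_design.shape[1]
    p = spec.latency_design.shape[1]
    fit.incidence_se = np.full(q, np.nan)
    fit.latency_se = np.full(p, np.nan)
    fit.incidence_ci = np.full((q, 2), np.nan)
    fit.latency_ci = np.full((p, 2), np.nan)
    fit.incidence_p = np.full(q, np.nan)
    fit.latency_p = np.full(p, np.nan)
    if se_method != "none":
        cure_se(fit, times, events, se_method=se_method, n_boot=n_boot, seed=seed)
    return fit


def cure_se(
    fit: CureModelFit,
    times,
    events,
    se_method: str = "bootstrap",
    n_boot: int = 200,
    seed: int = None,
) -> CureModelFit:
    """Attach standard errors, 95% CIs and p-values to a cure-model fit.

    Bootstrap (default): patients resampled with replacement, the EM refitted,
    percentile 2.5/97.5 CIs taken; p-values are Wald using the bootstrap SE.
    Deterministic for a fixed seed. If more than 20% of refits fail to
    converge a warning reports the achieved count. "numeric-hessian" uses the
    observed-likelihood Hessian (recommended only for the Weibull latency).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    spec = fit.spec
    q = spec.incidence_design.shape[1]
    p = spec.latency_design.shape[1]

    if se_method == "numeric-hessian":
        theta0 = np.concatenate([fit.params.incidence_coefs, fit.params.latency_coefs])

        def ll_at(theta):
            pr = replace(
                fit.params, incidence_coefs=theta[:q], latency_coefs=theta[q:]
            )
            return observed_loglik(pr, times, events, spec)

        H = _numeric_hessian(ll_at, theta0)
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        b_se, beta_se = se[:q], se[q:]
        n_conv = 0
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(times)
        draws = np.full((n_boot, q + p), np.nan)
        n_conv = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                if events[idx].sum() == 0:
                    continue
                sub = CureModelSpec(
                    spec.incidence_design[idx],
                    spec.latency_design[idx],
                    spec.incidence_names,
                    spec.latency_names,
                    spec.latency_form,
                )
                try:
                    bf = fit_mixture_cure(
                        times[idx], events[idx], sub, max_iter=200, tol=1e-5, se_method="none"
                    )
                except Exception:
                    continue
                if bf.converged:
                    n_conv += 1
                    draws[b] = np.concatenate(
                        [bf.params.incidence_coefs, bf.params.latency_coefs]
                    )
        ok = np.isfinite(draws).all(axis=1)
        if n_conv < 0.8 * n_boot:
            warnings.warn(
                f"only {n_conv}/{n_boot} bootstrap refits converged", stacklevel=2
            )
        if ok.sum() < 2:
            raise UndefinedInputError("too few successful bootstrap refits")
        dd = draws[ok]
        se = dd.std(axis=0, ddof=1)
        lo = np.percentile(dd, 2.5, axis=0)
        hi = np.percentile(dd, 97.5, axis=0)
        b_se, beta_se = se[:q], se[q:]
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    est_b = fit.params.incidence_coefs
    est_beta = fit.params.latency_coefs
    if se_method == "bootstrap":
        fit.incidence_ci = np.exp(np.column_stack([lo[:q], hi[:q]]))
        fit.latency_ci = np.exp(np.column_stack([lo[q:], hi[q:]]))
    else:
        fit.incidence_ci = np.exp(
            np.column_stack([est_b - _Z975 * b_se, est_b + _Z975 * b_se])
        )
        fit.latency_ci = np.exp(
            np.column_stack([est_beta - _Z975 * beta_se, est_beta + _Z975 * beta_se])
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fit.incidence_p = 2.0 * stats.norm.sf(np.abs(est_b / b_se))
        fit.latency_p = 2.0 * stats.norm.sf(np.abs(est_beta / beta_se))
    fit.incidence_se = b_se
    fit.latency_se = beta_se
    fit.se_method = se_method
    fit.n_boot_requested = n_boot if se_method == "bootstrap" else 0
    fit.n_boot_converged = n_conv if se_method == "bootstrap" else 0
    return fit


def _numeric_hessian(f, x0, eps=1e-5):
    k = len(x0)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def summary_frame(fit: CureModelFit):
    """Tidy per-coefficient summary: component, name, OR/HR, CI, p."""
    import pandas as pd

    rows = []
    for i, name in enumerate(fit.spec.incidence_names):
        rows.append(
            {
                "component": "incidence",
                "name": name,
                "estimate": fit.incidence_or[i],
                "scale": "OR",
                "ci_low": fit.incidence_ci[i, 0],
                "ci_high": fit.incidence_ci[i, 1],
                "p": fit.incidence_p[i],
            }
        )
    for i, name in enumerate(fit.spec.latency_names):
        rows.append(
            {
                "component": "latency",
                "name": name,
                "estimate": fit.latency_hr[i],
                "scale": "HR",
                "ci_low": fit.latency_ci[i, 0],
                "ci_high": fit.latency_ci[i, 1],
                "p": fit.latency_p[i],
            }
        )
    return pd.DataFrame(rows)
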