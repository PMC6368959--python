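"""Low-level fitting engines: weighted Cox partial likelihood and IRLS logistic.

These are the numerical workhorses shared by the public survival module and
the mixture cure model's EM loop. They operate on plain numpy arrays, accept
per-subject case weights and linear offsets, and are written so that a single
fit on a few hundred subjects costs microseconds — a genome-wide scan calls
them tens of thousands of times.

Conventions
-----------
* ``times`` strictly positive, ``events`` in {0,1}; subjects with weight 0 are
  dropped from all risk sets.
* Ties: "efron" (default) or "breslow", both in their case-weighted form.
* The returned ``information`` is the negative Hessian of the weighted partial
  log-likelihood at the estimate; ``covariance`` is its inverse.
* The baseline cumulative hazard is the weighted Breslow estimator evaluated
  at the distinct event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CollinearityError, NoEventsError

# Cap applied when the partial/binomial likelihood is monotone (separation):
# coefficients beyond this are not meaningfully estimable on cohort-scale data.
COEF_CAP = 15.0


@dataclass
class CoxEngineResult:
    beta: np.ndarray
    covariance: np.ndarray
    information: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    monotone_likelihood: bool
    # distinct event times and the weighted Breslow hazard increments there
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_hazard: np.ndarray = field(default_factory=lambda: np.empty(0))


def _prepare(times, events, X, weights, offset):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = times.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    keep = w > 0
    if not keep.all():
        times, events, X, w, off = times[keep], events[keep], X[keep], w[keep], off[keep]
    order = np.argsort(times, kind="stable")
    return times[order], events[order], X[order], w[order], off[order]


_TRIU_CACHE: dict = {}


def _triu(p):
    if p not in _TRIU_CACHE:
        _TRIU_CACHE[p] = np.triu_indices(p)
    return _TRIU_CACHE[p]


def _suffix_sums(r, X):
    """Suffix (right-to-left cumulative) sums of r, r*x, r*x*x' for sorted data."""
    n, p = X.shape
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    # upper-triangle packing of the p x p second-moment suffix sums
    iu, ju = _triu(p)
    s2flat = np.cumsum((r[:, None] * X[:, iu] * X[:, ju])[::-1], axis=0)[::-1]
    return s0, s1, s2flat, (iu, ju)


def _unpack_sym(flat, p, iu_ju):
    iu, ju = iu_ju
    m = np.zeros((p, p))
    m[iu, ju] = flat
    m[ju, iu] = flat
    return m


def _loglik_grad_hess(beta, times, events, X, w, off, ties):
    """Weighted partial log-likelihood, gradient and negative Hessian.

    Data must be sorted by time ascending. Uses a fully vectorized path when
    all event times are distinct (Efron == Breslow there), else a grouped loop
    over tied death times.
    """
    n, p = X.shape
    eta = X @ beta + off
    eta = np.clip(eta, -500, 500)
    r = w * np.exp(eta)
    s0, s1, s2flat, iu_ju = _suffix_sums(r, X)
    ev = events == 1
    d_idx = np.flatnonzero(ev)
    dtimes = times[d_idx]

    # first index of each subject's own time (risk set = time >= t)
    first = np.searchsorted(times, dtimes, side="left")

    ll = float(np.sum(w[d_idx] * eta[d_idx]))
    grad = (w[d_idx, None] * X[d_idx]).sum(axis=0)
    hess = np.zeros((p, p))

    unique_d, d_start, d_count = np.unique(dtimes, return_index=True, return_counts=True)
    if d_count.max(initial=0) <= 1:
        # no tied deaths: one Breslow term per event
        S0 = s0[first]
        S1 = s1[first]
        S2f = s2flat[first]
        wd = w[d_idx]
        ll -= float(np.sum(wd * np.log(S0)))
        mean = S1 / S0[:, None]
        grad -= (wd[:, None] * mean).sum(axis=0)
        iu, ju = iu_ju
        hflat = (wd[:, None] * (S2f / S0[:, None] - mean[:, iu] * mean[:, ju])).sum(axis=0)
        hess[iu, ju] = hflat
        hess[ju, iu] = hflat
    else:
        for t0, st, d in zip(unique_d, d_start, d_count):
            D = d_idx[st : st + d]
            fi = np.searchsorted(times, t0, side="left")
            S0R, S1R = s0[fi], s1[fi]
            S2R = _unpack_sym(s2flat[fi], p, iu_ju)
            wsum = float(w[D].sum())
            if ties == "breslow" or d == 1:
                ll -= wsum * np.log(S0R)
                mean = S1R / S0R
                grad -= wsum * mean
                hess += wsum * (S2R / S0R - np.outer(mean, mean))
            else:  # efron
                rD = r[D]
                S0D = rD.sum()
                S1D = (rD[:, None] * X[D]).sum(axis=0)
                S2D = (rD[:, None, None] * X[D][:, :, None] * X[D][:, None, :]).sum(axis=0)
                for k in range(d):
                    f = k / d
                    S0k = S0R - f * S0D
                    S1k = S1R - f * S1D
                    S2k = S2R - f * S2D
                    ll -= (wsum / d) * np.log(S0k)
                    mean = S1k / S0k
                    grad -= (wsum / d) * mean
                    hess += (wsum / d) * (S2k / S0k - np.outer(mean, mean))
    return ll, grad, hess


def cox_loglik(beta, times, events, X, weights=None, offset=None, ties="efron"):
    """Weighted Cox partial log-likelihood at ``beta`` (sorting handled here)."""
    times, events, X, w, off = _prepare(times, events, X, weights, offset)
    if events.sum() == 0:
        raise NoEventsError("partial likelihood undefined without events")
    ll, _, _ = _loglik_grad_hess(np.asarray(beta, float), times, events, X, w, off, ties)
    return ll


def cox_newton(
    times,
    events,
    X,
    weights=None,
    offset=None,
    ties="efron",
    max_iter=100,
    tol=1e-9,
    init=None,
    compute_null=True,
) -> CoxEngineResult:
    """Maximize the (weighted) Cox partial likelihood by damped Newton-Raphson.

    Monotone likelihood (separation) is detected when a coefficient runs past
    ``COEF_CAP``; the fit is returned at the capped value with the
    ``monotone_likelihood`` flag set rather than raising.
    """
    times, events, X, w, off = _prepare(times, events, X, weights, offset)
    n, p = X.shape
    if events.sum() == 0:
        raise NoEventsError("Cox fit requires at least one event")
    if p == 0:
        # baseline-only model: nothing to optimize
        ll0, _, _ = _loglik_grad_hess(np.zeros(0), times, events, X, w, off, ties)
        ev_times, haz = _breslow_increments(np.zeros(0), times, events, X, w, off)
        return CoxEngineResult(
            beta=np.zeros(0),
            covariance=np.zeros((0, 0)),
            information=np.zeros((0, 0)),
            loglik=ll0,
            loglik_null=ll0,
            n_iter=0,
            converged=True,
            monotone_likelihood=False,
            event_times=ev_times,
            baseline_hazard=haz,
        )
    # rank check on the (weighted) design among subjects actually at risk
    Xc = X - np.average(X, axis=0, weights=w)
    if np.linalg.matrix_rank((Xc * w[:, None]).T @ Xc) < p:
        raise CollinearityError("design matrix is rank deficient")

    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    ll, grad, hess = _loglik_grad_hess(beta, times, events, X, w, off, ties)
    if compute_null:
        ll0 = (
            ll
            if init is None
            else _loglik_grad_hess(np.zeros(p), times, events, X, w, off, ties)[0]
        )
    else:
        ll0 = np.nan

    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("singular information matrix") from exc
        # step halving if the likelihood does not improve
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_grad_hess(new_beta, times, events, X, w, off, ties)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            halvings += 1
            if halvings > 30:
                break
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_grad_hess(
                new_beta, times, events, X, w, off, ties
            )
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta).max() > COEF_CAP:
            monotone = True
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            ll, grad, hess = _loglik_grad_hess(beta, times, events, X, w, off, ties)
            break
        if np.abs(step).max() < tol or np.abs(grad).max() < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)

    ev_times, haz = _breslow_increments(beta, times, events, X, w, off)
    return CoxEngineResult(
        beta=beta,
        covariance=cov,
        information=hess,
        loglik=ll,
        loglik_null=ll0,
        n_iter=it,
        converged=converged,
        monotone_likelihood=monotone,
        event_times=ev_times,
        baseline_hazard=haz,
    )


def _breslow_increments(beta, times, events, X, w, off):
    """Weighted Breslow baseline hazard increments at distinct event times."""
    eta = np.clip(X @ beta + off, -500, 500)
    r = w * np.exp(eta)
    s0 = np.cumsum(r[::-1])[::-1]
    d_idx = np.flatnonzero(events == 1)
    dtimes = times[d_idx]
    unique_d, d_start, d_count = np.unique(dtimes, return_index=True, return_counts=True)
    wsums = np.add.reduceat(w[d_idx], d_start)
    first = np.searchsorted(times, unique_d, side="left")
    return unique_d, wsums / s0[first]


def schoenfeld_residuals(beta, times, events, X, weights=None, offset=None):
    """Per-event Schoenfeld residuals x_i - xbar(t_i), sorted by event time.

    Within tied death times the risk-set weighted mean (Breslow form) is used.
    Returns (event_times, residual matrix of shape n_events x p).
    """
    times, events, X, w, off = _prepare(times, events, X, weights, offset)
    eta = np.clip(X @ beta + off, -500, 500)
    r = w * np.exp(eta)
    s0, s1, _, _ = _suffix_sums(r, X)
    d_idx = np.flatnonzero(events == 1)
    first = np.searchsorted(times, times[d_idx], side="left")
    xbar = s1[first] / s0[first][:, None]
    return times[d_idx], X[d_idx] - xbar


def logistic_irls(Z, y, weights=None, max_iter=100, tol=1e-10, init=None):
    """Weighted logistic regression by IRLS, fractional responses allowed.

    Returns (beta, covariance, converged, capped). Separation is handled by
    capping |beta| at COEF_CAP with ``capped`` set, never by divergence.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    converged = False
    capped = False

    def ll_at(b):
        eta = np.clip(Z @ b, -30, 30)
        return float(np.sum(w * (y * eta - np.log1p(np.exp(eta)))))

    ll = ll_at(beta)
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = w * mu * (1.0 - mu) + 1e-12
        grad = Z.T @ (w * (y - mu))
        H = (Z * wt[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("singular information in logistic fit") from exc
        # step-halving: IRLS full steps can overshoot near separation, and
        # the EM wrapper requires every M-step to be an ascent
        new_beta = beta + step
        new_ll = ll_at(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll = ll_at(new_beta)
            halvings += 1
        beta, ll = new_beta, new_ll
        if np.abs(beta).max() > COEF_CAP:
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            capped = True
            break
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = np.clip(Z @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    wt = w * mu * (1.0 - mu) + 1e-12
    H = (Z * wt[:, None]).T @ Z
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged, capped
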