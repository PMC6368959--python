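"""Kaplan-Meier estimation, log-rank tests, Cox PH fits and the PH score test.

These are the building blocks of the scan's non-cure branches. Time is
measured in years from diagnosis; the event is distant metastasis; subjects
without an event are right-censored at last follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._engines import cox_newton, schoenfeld_residuals
from .exceptions import NoEventsError, UndefinedInputError


@dataclass
class KmCurve:
    """Product-limit estimate of the survival function.

    ``event_times`` lists the distinct times with >= 1 event; ``survival`` the
    estimate just after each of those times. ``max_followup`` is the largest
    observed time, event or censored, so ``long_term_estimate`` can read the
    plateau off the curve.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    max_followup: float
    n: int

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous, S=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class CoxFit:
    """A fitted Cox proportional hazards model with Wald inference."""

    names: list
    coefficients: np.ndarray
    covariance: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    wald_p: np.ndarray
    partial_loglik: float
    partial_loglik_null: float
    converged: bool
    monotone_likelihood: bool
    n: int
    n_events: int
    ties: str
    baseline_event_times: np.ndarray
    baseline_hazard: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def lr_test(self) -> tuple[float, float]:
        """Likelihood-ratio test of the full model against the null model."""
        stat = 2.0 * (self.partial_loglik - self.partial_loglik_null)
        stat = max(stat, 0.0)
        df = len(self.coefficients)
        return stat, float(stats.chi2.sf(stat, df))


@dataclass
class PhTestResult:
    """Grambsch-Therneau score test for proportional hazards."""

    names: list
    statistics: np.ndarray
    p_values: np.ndarray
    global_statistic: float
    global_p: float
    time_transform: str


def kaplan_meier(times, events) -> KmCurve:
    """Product-limit survival estimate.

    An all-censored sample yields survival identically 1 (no event times).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise UndefinedInputError("Kaplan-Meier estimate requires at least one subject")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = t.size
    ut, start, count = np.unique(t, return_index=True, return_counts=True)
    d = np.add.reduceat(e, start)  # events per distinct time
    at_risk = n - start  # subjects with time >= ut
    has_event = d > 0
    ev_t = ut[has_event]
    n_risk = at_risk[has_event]
    n_event = d[has_event]
    surv = np.cumprod(1.0 - n_event / n_risk)
    return KmCurve(
        event_times=ev_t,
        survival=surv,
        n_risk=n_risk,
        n_event=n_event,
        max_followup=float(t[-1]),
        n=n,
    )


def long_term_estimate(curve: KmCurve) -> float:
    """KM survival at the group's own last follow-up: the plateau value.

    1 for an event-free group; 0 when the last subject at risk has an event.
    """
    return curve.at(curve.max_followup)


def log_rank_test(groups) -> tuple[float, int, float]:
    """Unweighted k-sample log-rank test.

    Parameters
    ----------
    groups : sequence of (times, events) pairs, each non-empty.

    Returns
    -------
    (chi-square statistic, degrees of freedom, p-value)
    """
    k = len(groups)
    if k < 2:
        raise UndefinedInputError("log-rank test needs at least two groups")
    times_list, events_list, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise UndefinedInputError(f"log-rank group {g} is empty")
        times_list.append(t)
        events_list.append(e)
        labels.append(np.full(t.size, g))
    t = np.concatenate(times_list)
    e = np.concatenate(events_list)
    g = np.concatenate(labels)

    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = t.size
    ut, start = np.unique(t, return_index=True)
    # group membership counts among subjects with time >= each distinct time
    G = np.zeros((n, k))
    G[np.arange(n), g] = 1.0
    risk_by_group = np.cumsum(G[::-1], axis=0)[::-1]  # suffix counts
    d_by_group = np.add.reduceat(G * e[:, None], start, axis=0)
    n_risk = (n - start).astype(float)
    d_tot = d_by_group.sum(axis=1)
    at_risk = risk_by_group[start]  # per distinct time, per group

    use = d_tot > 0
    d_tot = d_tot[use]
    d_by_group = d_by_group[use]
    n_risk = n_risk[use]
    at_risk = at_risk[use]
    if d_tot.size == 0:
        return 0.0, k - 1, 1.0

    O = d_by_group.sum(axis=0)
    E = (at_risk * (d_tot / n_risk)[:, None]).sum(axis=0)
    # hypergeometric covariance, summed over distinct event times
    V = np.zeros((k, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = d_tot * (n_risk - d_tot) / np.where(n_risk > 1, n_risk - 1, 1.0)
    prop = at_risk / n_risk[:, None]
    for j in range(k):
        for l in range(j, k):
            delta = 1.0 if j == l else 0.0
            V[j, l] = V[l, j] = np.sum(factor * prop[:, j] * (delta - prop[:, l]))
    # drop the last group (covariance matrix is singular over all k)
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def cox_fit(times, events, design, names=None, ties="efron", weights=None, offset=None) -> CoxFit:
    """Fit a Cox proportional hazards model by penalized-free Newton iteration.

    Wald 95% confidence intervals and p-values are reported per covariate.
    Monotone likelihood (complete separation of event order) is flagged on the
    returned fit rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    res = cox_newton(times, events, design, weights=weights, offset=offset, ties=ties)
    se = np.sqrt(np.clip(np.diag(res.covariance), 0.0, np.inf))
    z = 1.959963984540054
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, res.beta / se, np.inf * np.sign(res.beta))
    p = 2.0 * stats.norm.sf(np.abs(wald))
    if names is None:
        names = [f"x{i}" for i in range(design.shape[1])]
    events_arr = np.asarray(events)
    return CoxFit(
        names=list(names),
        coefficients=res.beta,
        covariance=res.covariance,
        hazard_ratios=np.exp(res.beta),
        ci_lower=np.exp(res.beta - z * se),
        ci_upper=np.exp(res.beta + z * se),
        wald_p=p,
        partial_loglik=res.loglik,
        partial_loglik_null=res.loglik_null,
        converged=res.converged,
        monotone_likelihood=res.monotone_likelihood,
        n=len(events_arr),
        n_events=int(events_arr.sum()),
        ties=ties,
        baseline_event_times=res.event_times,
        baseline_hazard=res.baseline_hazard,
    )


def _transform_times(times, events, transform):
    """Map event times to the scale used by the PH score test."""
    ev_t = np.sort(np.asarray(times, float)[np.asarray(events) == 1])
    if transform == "identity":
        return ev_t
    if transform == "log":
        return np.log(ev_t)
    if transform == "km":
        km = kaplan_meier(times, events)
        # right-continuous KM at each event time (reference-implementation form)
        idx = np.searchsorted(km.event_times, ev_t, side="right")
        s_plus = np.concatenate([[1.0], km.survival])[idx]
        return 1.0 - s_plus
    if transform == "rank":
        return stats.rankdata(ev_t)
    raise ValueError(f"unknown time transform {transform!r}")


def ph_score_test(fit: CoxFit, times, events, design, time_transform="km") -> PhTestResult:
    """Score test for proportional hazards from scaled Schoenfeld residuals.

    The Grambsch-Therneau construction: regress the Schoenfeld residuals on a
    transform g(t) of event time; under proportional hazards the slope is zero.
    Per-covariate statistics are chi-square with 1 df, the global statistic has
    one df per covariate. The statistic is invariant to affine changes of g.
    """
    if not fit.converged and not fit.monotone_likelihood:
        raise UndefinedInputError("PH score test requires a converged Cox fit")
    events_arr = np.asarray(events, dtype=int)
    if events_arr.sum() == 0:
        raise NoEventsError("PH score test undefined without events")
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    ev_times, resid = schoenfeld_residuals(fit.coefficients, times, events_arr, design)
    d = resid.shape[0]
    g = _transform_times(times, events_arr, time_transform)
    gc = g - g.mean()
    denom_g = float(np.sum(gc**2))
    u = resid.T @ gc  # p-vector
    Iinv_u = fit.covariance @ u
    global_stat = float(d * (u @ Iinv_u) / denom_g)
    per = d * (Iinv_u**2) / (np.diag(fit.covariance) * denom_g)
    per = np.maximum(per, 0.0)
    global_stat = max(global_stat, 0.0)
    p = stats.chi2.sf(per, 1)
    return PhTestResult(
        names=fit.names,
        statistics=per,
        p_values=p,
        global_statistic=global_stat,
        global_p=float(stats.chi2.sf(global_stat, design.shape[1])),
        time_transform=time_transform,
    )


def plot_km(curves: dict, path=None, ax=None, title=None):
    """Step-plot labelled KM curves; convenience output for reports.

    ``curves`` maps a group label to a KmCurve. Writes to ``path`` (SVG/PNG by
    extension) when given, otherwise draws on ``ax``/a new figure.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times, [curve.max_followup]])
        s = np.concatenate([[1.0], curve.survival, [curve.survival[-1] if curve.survival.size else 1.0]])
        ax.step(t, s, where="post", label=str(label))
    ax.set_xlabel("years from diagnosis")
    ax.set_ylabel("metastasis-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
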