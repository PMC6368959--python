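"""Baseline-covariate selection for multivariable adjustment.

Selection runs separately per model family because a covariate can matter
for the long-term risk of metastasis (incidence), for its timing among the
susceptible (latency), or for the plain Cox hazard — and the two families
weigh these differently:

* mixture-cure family — a covariate qualifies if it is associated with
  either component; its p-value for screening/removal is the smaller of the
  incidence and latency likelihood-ratio p-values;
* cox family — the joint likelihood-ratio p for the covariate's levels.

The procedure is the classic two-stage screen: univariable entry at a
liberal threshold (default 0.10), then backward elimination at 0.05 with an
optional forced-in set (forced variables are never removed, whatever their
p). All tests are likelihood-ratio tests with one df per dummy column per
component, which handles multi-level covariates jointly and keeps the trace
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cure import CureModelSpec, fit_mixture_cure
from .design import categorical_design, covariate_groups
from .exceptions import ConvergenceError
from .survival import cox_fit

MODEL_FAMILIES = ("mixture-cure", "cox")


@dataclass
class CandidateResult:
    """Univariable screen result for one covariate."""

    name: str
    p_incidence: float
    p_latency: float
    p: float
    entered: bool
    note: str = ""


@dataclass
class SelectionTrace:
    """Full record of a backward-selection run."""

    model_family: str
    candidates: list
    forced: list
    drops: list = field(default_factory=list)  # (name, removal p) in drop order
    final: list = field(default_factory=list)
    final_p: dict = field(default_factory=dict)
    n_used: int = 0


def _cure_loglik(times, events, X):
    n = len(times)
    Z = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    spec = CureModelSpec(Z, X)
    fit = fit_mixture_cure(times, events, spec, se_method="none")
    return fit.observed_loglik, fit.converged


def _family_pvalues(times, events, design, groups, family):
    """Per-covariate LR p-values for dropping each variable from a full fit.

    For the cure family returns (p_incidence, p_latency) per variable; for
    cox a single p. Raises ConvergenceError if the full fit fails.
    """
    if family == "cox":
        full = cox_fit(times, events, design)
        if not full.converged and not full.monotone_likelihood:
            raise ConvergenceError("full Cox fit did not converge")
        out = {}
        for name, cols in groups.items():
            keep = [i for i in range(design.shape[1]) if i not in cols]
            red = cox_fit(times, events, design[:, keep]) if keep else None
            ll0 = red.partial_loglik if red else full.partial_loglik_null
            lr = max(2.0 * (full.partial_loglik - ll0), 0.0)
            out[name] = (float(stats.chi2.sf(lr, len(cols))),)
        return out

    ll_full, conv = _cure_loglik(times, events, design)
    if not conv:
        raise ConvergenceError("full mixture-cure fit did not converge")
    n = len(times)
    out = {}
    for name, cols in groups.items():
        keep = [i for i in range(design.shape[1]) if i not in cols]
        k = len(cols)
        # drop from incidence only
        Z0 = np.column_stack([np.ones(n), design[:, keep]])
        spec_inc = CureModelSpec(Z0, design)
        f_inc = fit_mixture_cure(times, events, spec_inc, se_method="none")
        lr_inc = max(2.0 * (ll_full - f_inc.observed_loglik), 0.0)
        # drop from latency only
        Zf = np.column_stack([np.ones(n), design])
        spec_lat = CureModelSpec(Zf, design[:, keep])
        f_lat = fit_mixture_cure(times, events, spec_lat, se_method="none")
        lr_lat = max(2.0 * (ll_full - f_lat.observed_loglik), 0.0)
        out[name] = (
            float(stats.chi2.sf(lr_inc, k)),
            float(stats.chi2.sf(lr_lat, k)),
        )
    return out


def univariable_screen(
    frame: pd.DataFrame,
    covariates,
    times,
    events,
    model_family: str,
    entry_p: float = 0.10,
) -> list:
    """Screen covariates one at a time at a liberal entry threshold.

    Patients with an unknown level of the covariate under test are excluded
    for that covariate only. Constant covariates are excluded with a note.
    Returns CandidateResult per covariate, in input order.
    """
    if model_family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cov in covariates:
            D, names, mask = categorical_design(frame, [cov])
            if D.shape[1] == 0:
                results.append(
                    CandidateResult(cov, np.nan, np.nan, np.nan, False, "constant covariate")
                )
                continue
            t, e = times[mask], events[mask]
            groups = covariate_groups(names)
            try:
                pv = _family_pvalues(t, e, D, {cov: groups[cov]}, model_family)[cov]
            except Exception as exc:
                results.append(
                    CandidateResult(cov, np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
                )
                continue
            if model_family == "mixture-cure":
                p_inc, p_lat = pv
                p = min(p_inc, p_lat)
            else:
                p_inc, p_lat = np.nan, pv[0]
                p = pv[0]
            results.append(CandidateResult(cov, p_inc, p_lat, p, bool(p < entry_p)))
    return results


def backward_select(
    frame: pd.DataFrame,
    candidates,
    forced,
    times,
    events,
    model_family: str,
    exit_p: float = 0.05,
) -> SelectionTrace:
    """Backward elimination with forced-in variables.

    Complete-case over candidates + forced. Each round refits the current
    model and removes the non-forced variable with the largest removal p
    >= ``exit_p`` (ties broken toward the variable later in the input
    order), until all non-forced variables are below the threshold. A
    non-convergent fit aborts with the trace accumulated so far attached to
    the raised ConvergenceError.
    """
    if model_family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = list(candidates) + [f for f in forced if f not in candidates]
    trace = SelectionTrace(model_family, list(candidates), list(forced))
    current = list(order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while True:
            D, names, mask = categorical_design(frame, current)
            groups = covariate_groups(names)
            t, e = times[mask], events[mask]
            trace.n_used = int(mask.sum())
            try:
                pvals = _family_pvalues(t, e, D, groups, model_family)
            except ConvergenceError as exc:
                exc.trace = trace
                raise
            removal = {
                name: min(pv) for name, pv in pvals.items() if name not in forced
            }
            trace.final_p = {name: min(pv) for name, pv in pvals.items()}
            over = {name: p for name, p in removal.items() if p >= exit_p}
            if not over:
                break
            worst_p = max(over.values())
            # tie-break: drop the variable later in the specified order
            worst = [n for n, p in over.items() if p == worst_p]
            drop = max(worst, key=order.index)
            trace.drops.append((drop, float(worst_p)))
            current.remove(drop)
            if not current:
                break
    trace.final = current
    return trace


def select_covariates(
    frame: pd.DataFrame,
    covariates,
    times,
    events,
    model_family: str,
    forced=(),
    entry_p: float = 0.10,
    exit_p: float = 0.05,
) -> tuple[list, SelectionTrace]:
    """Screen then backward-select; returns (screen results, trace)."""
    screen = univariable_screen(frame, covariates, times, events, model_family, entry_p)
    candidates = [c.name for c in screen if c.entered]
    trace = backward_select(frame, candidates, list(forced), times, events, model_family, exit_p)
    return screen, trace


def trace_frame(trace: SelectionTrace) -> pd.DataFrame:
    """SelectionTrace -> tidy DataFrame for TSV output."""
    rows = [
        {"step": i + 1, "action": "drop", "variable": name, "p": p}
        for i, (name, p) in enumerate(trace.drops)
    ]
    for name in trace.final:
        rows.append(
            {
                "step": len(trace.drops) + 1,
                "action": "keep" + (" (forced)" if name in trace.forced else ""),
                "variable": name,
                "p": trace.final_p.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows)
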