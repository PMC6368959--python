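"""Genome-wide scan engine: genetic-model encoding, plateau-based routing,
per-SNP fitting, genetic-model validity testing and multivariable refits.

For every SNP x genetic model the scan

1. encodes the minor-allele count under the model (additive: allele count;
   dominant: any minor allele; recessive: minor-homozygote; co-dominant: two
   free genotype indicators, which nests the other three);
2. computes the Kaplan-Meier long-term (plateau) survival estimate for each
   genotype category of that encoding and routes the SNP to an analysis
   method: every plateau strictly inside (0, 1) -> mixture cure model; any
   category event-free (plateau 1) -> log-rank test; otherwise a category
   with plateau 0 -> Cox proportional hazards. Categories with fewer than 2
   patients make the SNP x model pair unanalyzable (skipped);
3. fits the routed method, recording estimates and a p-value. Cure-branch
   p-values default to likelihood-ratio tests against the intercept-only
   cure model (the null fit is shared across SNPs), which keeps a scan of
   10^5 SNPs tractable; bootstrap Wald inference remains available through
   the cure module for reported hits.

Bonferroni control divides alpha by the number of SNPs scanned (not
SNP x model pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort_io import MISSING, GenotypeMatrix
from .cure import CureModelSpec, cure_se, fit_mixture_cure, observed_loglik
from .exceptions import UndefinedInputError
from .survival import cox_fit, kaplan_meier, log_rank_test, long_term_estimate, ph_score_test

GENETIC_MODELS = ("additive", "dominant", "recessive", "codominant")

#: minimum patients per genotype category for a model to be analyzable
MIN_CATEGORY_SIZE = 2


def encode(codes, model: str):
    """Encode minor-allele counts under a genetic model.

    Returns (design matrix over non-missing patients, non-missing mask,
    category labels, per-category patient counts). Categories are the groups
    the fitted model actually contrasts: the two collapsed groups for
    dominant/recessive, the three raw genotypes for co-dominant and additive
    (an additive trend is undefined on collapsed categories).
    """
    codes = np.asarray(codes)
    obs = codes != MISSING
    x = codes[obs].astype(float)
    if model == "additive":
        design = x[:, None]
        labels = ["0", "1", "2"]
        cats = [x == 0, x == 1, x == 2]
    elif model == "dominant":
        design = (x >= 1).astype(float)[:, None]
        labels = ["0", "1|2"]
        cats = [x == 0, x >= 1]
    elif model == "recessive":
        design = (x == 2).astype(float)[:, None]
        labels = ["0|1", "2"]
        cats = [x < 2, x == 2]
    elif model == "codominant":
        design = np.column_stack([(x == 1).astype(float), (x == 2).astype(float)])
        labels = ["0", "1", "2"]
        cats = [x == 0, x == 1, x == 2]
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    counts = np.array([int(c.sum()) for c in cats])
    return design, obs, labels, counts


@dataclass
class RoutingDecision:
    """Which analysis method a SNP x genetic model pair is sent to."""

    snp_id: str
    model: str
    category_labels: list
    category_counts: np.ndarray
    plateaus: np.ndarray  # long-term KM estimate per category (NaN when skipped)
    method: str  # mixture-cure | cox | log-rank | skipped
    skip_reason: str = ""


def route(codes, model: str, times, events, snp_id: str = "") -> RoutingDecision:
    """Apply the plateau rules to one SNP under one genetic model.

    Log-rank takes precedence when both an event-free and an all-event
    category exist, since neither survival model is then fitted.
    """
    design, obs, labels, counts = encode(codes, model)
    times = np.asarray(times, float)[obs]
    events = np.asarray(events, int)[obs]
    if (counts < MIN_CATEGORY_SIZE).any():
        return RoutingDecision(
            snp_id,
            model,
            labels,
            counts,
            np.full(len(labels), np.nan),
            "skipped",
            f"genotype category with <{MIN_CATEGORY_SIZE} patients",
        )
    codes_obs = np.asarray(codes)[obs]
    if model == "dominant":
        groups = [codes_obs == 0, codes_obs >= 1]
    elif model == "recessive":
        groups = [codes_obs < 2, codes_obs == 2]
    else:  # additive, codominant: raw genotype categories
        groups = [codes_obs == 0, codes_obs == 1, codes_obs == 2]
    plateaus = np.array(
        [long_term_estimate(kaplan_meier(times[g], events[g])) for g in groups]
    )
    if (plateaus >= 1.0).any():
        method = "log-rank"
    elif ((plateaus > 0.0) & (plateaus < 1.0)).all():
        method = "mixture-cure"
    else:
        method = "cox"
    return RoutingDecision(snp_id, model, labels, counts, plateaus, method)


@dataclass
class ScanResult:
    """One row of the scan: SNP x genetic model."""

    snp_id: str
    model: str
    method: str
    n_used: int = 0
    n_events: int = 0
    routing: RoutingDecision = None
    term_names: list = field(default_factory=list)
    # univariable estimates; ORs only for the cure branch
    or_est: np.ndarray = None
    hr_est: np.ndarray = None
    p_value: float = np.nan  # the scan p (LR for cure/cox, chi2 for log-rank)
    genotype_freq: float = np.nan  # frequency of the tested (exposed) category
    validity: str = "not-applicable"  # plausible | rejected | not-applicable
    validity_p: float = np.nan
    ph_p: float = np.nan  # proportionality score test (cox branch)
    significant: bool = False
    converged: bool = True
    error: str = ""
    # multivariable adjustment (filled by multivariable_refit)
    adjusted: bool = False
    adj_or: np.ndarray = None
    adj_hr: np.ndarray = None
    adj_p: float = np.nan
    adj_n: int = 0
    # identified-model vs co-dominant coefficients (filled by model_validity)
    coef_comparison: dict = None


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error control: alpha divided by the number of tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise UndefinedInputError("Bonferroni threshold undefined for n_tests < 1")
    return alpha / n_tests


def _tested_category_freq(counts, model):
    tot = counts.sum()
    if model == "dominant":
        return counts[1] / tot
    if model == "recessive":
        return counts[-1] / tot
    # additive / codominant: minor-allele frequency of the used patients
    n0, n1, n2 = counts
    return (n1 + 2 * n2) / (2.0 * tot)


def _cure_lr_fit(times, events, design, null_fit):
    """Cure fit of a SNP design plus LR p against the shared null fit.

    The alternative is warm-started from the null parameters (zero-padded),
    which roughly halves EM iterations under the null.
    """
    from .cure import CureParams

    n = len(times)
    k = design.shape[1]
    Z = np.column_stack([np.ones(n), design])
    spec = CureModelSpec(Z, design)
    init = CureParams(
        incidence_coefs=np.concatenate([null_fit.params.incidence_coefs, np.zeros(k)]),
        latency_coefs=np.zeros(k),
        event_times=null_fit.params.event_times,
        baseline_hazard=null_fit.params.baseline_hazard,
    )
    fit = fit_mixture_cure(times, events, spec, se_method="none", init_params=init)
    lr = max(2.0 * (fit.observed_loglik - null_fit.observed_loglik), 0.0)
    p = float(stats.chi2.sf(lr, 2 * k))
    return fit, p


def univariable_scan(
    matrix: GenotypeMatrix,
    times,
    events,
    models=GENETIC_MODELS,
    alpha: float = 0.05,
    n_tests: int = None,
    p_method: str = "lr",
    ph_alpha: float = 0.05,
    seed: int = None,
) -> list:
    """Scan every SNP under every requested genetic model.

    Per-SNP fit failures are captured in the result row (``error`` field),
    never aborting the scan. ``n_tests`` defaults to the number of SNPs.
    Returns a list of ScanResult.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if n_tests is None:
        n_tests = matrix.n_snps
    threshold = bonferroni_threshold(alpha, n_tests)

    # cache the cure-branch null fit per missingness pattern
    null_cache: dict = {}

    results = []
    for i, meta in enumerate(matrix.snps):
        codes = matrix.codes[i]
        for model in models:
            dec = route(codes, model, times, events, snp_id=meta.snp_id)
            res = ScanResult(meta.snp_id, model, dec.method, routing=dec)
            if dec.method == "skipped":
                results.append(res)
                continue
            design, obs, labels, counts = encode(codes, model)
            t, e = times[obs], events[obs]
            res.n_used = int(obs.sum())
            res.n_events = int(e.sum())
            res.genotype_freq = float(_tested_category_freq(counts, model))
            try:
                if dec.method == "mixture-cure":
                    key = obs.tobytes()
                    if key not in null_cache:
                        nspec = CureModelSpec(np.ones((len(t), 1)), np.zeros((len(t), 0)))
                        null_cache[key] = fit_mixture_cure(t, e, nspec, se_method="none")
                    if p_method == "lr":
                        fit, p = _cure_lr_fit(t, e, design, null_cache[key])
                    else:  # bootstrap Wald
                        Z = np.column_stack([np.ones(len(t)), design])
                        fit = fit_mixture_cure(
                            t, e, CureModelSpec(Z, design),
                            se_method="bootstrap", seed=seed,
                        )
                        p = float(
                            np.nanmin(
                                np.concatenate([fit.incidence_p[1:], fit.latency_p])
                            )
                        )
                    res.term_names = labels[1:] if model != "additive" else ["trend"]
                    res.or_est = np.exp(fit.params.incidence_coefs[1:])
                    res.hr_est = np.exp(fit.params.latency_coefs)
                    res.p_value = p
                    res.converged = fit.converged
                elif dec.method == "cox":
                    fit = cox_fit(t, e, design)
                    lr_stat, p = fit.lr_test()
                    res.term_names = labels[1:] if model != "additive" else ["trend"]
                    res.hr_est = fit.hazard_ratios
                    res.p_value = p
                    res.converged = fit.converged and not fit.monotone_likelihood
                    if p < threshold:
                        ph = ph_score_test(fit, t, e, design)
                        res.ph_p = float(ph.global_p)
                else:  # log-rank
                    codes_obs = np.asarray(codes)[obs]
                    if model == "dominant":
                        groups = [codes_obs == 0, codes_obs >= 1]
                    elif model == "recessive":
                        groups = [codes_obs < 2, codes_obs == 2]
                    else:
                        groups = [codes_obs == 0, codes_obs == 1, codes_obs == 2]
                    stat, df, p = log_rank_test([(t[g], e[g]) for g in groups])
                    res.p_value = p
                res.significant = bool(res.p_value < threshold)
            except Exception as exc:  # captured per row, scan continues
                res.error = f"{type(exc).__name__}: {exc}"
                res.significant = False
            results.append(res)
    return results


def model_validity(
    result: ScanResult,
    codes,
    times,
    events,
    alpha: float = 0.05,
) -> ScanResult:
    """Likelihood-ratio check of the identified genetic model.

    The co-dominant encoding nests additive, dominant and recessive; a
    significant improvement of the co-dominant fit (same method branch, same
    patients) rejects the identified model. When no minor homozygotes exist
    the co-dominant model coincides with the dominant one: the LR statistic
    is zero and the model stands. Returns an updated copy of ``result``.
    """
    if result.model == "codominant" or result.method in ("log-rank", "skipped"):
        return replace(result, validity="not-applicable", validity_p=np.nan)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    design_id, obs, _, _ = encode(codes, result.model)
    design_co, _, _, _ = encode(codes, "codominant")
    t, e = times[obs], events[obs]
    # drop empty co-dominant indicator columns (absent genotype category)
    keep = design_co.sum(axis=0) > 0
    design_co = design_co[:, keep]
    k_id, k_co = design_id.shape[1], design_co.shape[1]
    try:
        if result.method == "mixture-cure":
            f_id = fit_mixture_cure(
                t, e, CureModelSpec(np.column_stack([np.ones(len(t)), design_id]), design_id),
                se_method="none",
            )
            f_co = fit_mixture_cure(
                t, e, CureModelSpec(np.column_stack([np.ones(len(t)), design_co]), design_co),
                se_method="none",
            )
            ll_id, ll_co = f_id.observed_loglik, f_co.observed_loglik
            df = 2 * (k_co - k_id)
            comparison = {
                "identified_or": np.exp(f_id.params.incidence_coefs[1:]),
                "codominant_or": np.exp(f_co.params.incidence_coefs[1:]),
                "identified_hr": np.exp(f_id.params.latency_coefs),
                "codominant_hr": np.exp(f_co.params.latency_coefs),
            }
        else:  # cox branch: partial likelihood
            f_id = cox_fit(t, e, design_id)
            f_co = cox_fit(t, e, design_co)
            ll_id, ll_co = f_id.partial_loglik, f_co.partial_loglik
            df = k_co - k_id
            comparison = {
                "identified_hr": f_id.hazard_ratios,
                "codominant_hr": f_co.hazard_ratios,
            }
    except Exception:
        return replace(result, validity="not-applicable", validity_p=np.nan)
    if df == 0:
        return replace(result, validity="plausible", validity_p=1.0, coef_comparison=comparison)
    lr = max(2.0 * (ll_co - ll_id), 0.0)
    p = float(stats.chi2.sf(lr, df))
    return replace(
        result,
        validity="rejected" if p < alpha else "plausible",
        validity_p=p,
        coef_comparison=comparison,
    )


def multivariable_refit(
    result: ScanResult,
    codes,
    times,
    events,
    covariate_design,
    covariate_mask,
    se_method: str = "none",
    seed: int = None,
) -> ScanResult:
    """Refit the routed method adjusting for baseline covariates.

    ``covariate_design``/``covariate_mask`` come from
    :func:`curescan.design.categorical_design` (complete-case: patients with
    unknown covariate levels are excluded, so n drops accordingly). The cure
    branch adjusts both the incidence and the latency component. Returns an
    updated copy of ``result``; non-convergence is recorded, not raised.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    codes = np.asarray(codes)
    _, obs, _, _ = encode(codes, result.model)
    use = obs & covariate_mask
    design_snp, _, _, _ = encode(codes[use], result.model)
    C = np.asarray(covariate_design, float)[use[covariate_mask]]
    t, e = times[use], events[use]
    out = replace(result)
    out.adj_n = int(use.sum())
    try:
        if result.method == "mixture-cure":
            X = np.column_stack([design_snp, C])
            Z = np.column_stack([np.ones(len(t)), X])
            fit = fit_mixture_cure(t, e, CureModelSpec(Z, X), se_method="none")
            k = design_snp.shape[1]
            # LR p for the SNP terms given covariates
            X0 = C
            Z0 = np.column_stack([np.ones(len(t)), C])
            fit0 = fit_mixture_cure(t, e, CureModelSpec(Z0, X0), se_method="none")
            lr = max(2.0 * (fit.observed_loglik - fit0.observed_loglik), 0.0)
            out.adj_p = float(stats.chi2.sf(lr, 2 * k))
            out.adj_or = np.exp(fit.params.incidence_coefs[1 : 1 + k])
            out.adj_hr = np.exp(fit.params.latency_coefs[:k])
            out.converged = fit.converged
            if se_method == "bootstrap":
                cure_se(fit, t, e, se_method="bootstrap", seed=seed)
        elif result.method == "cox":
            X = np.column_stack([design_snp, C])
            fit = cox_fit(t, e, X)
            k = design_snp.shape[1]
            fit0 = cox_fit(t, e, C) if C.shape[1] else None
            ll0 = fit0.partial_loglik if fit0 is not None else fit.partial_loglik_null
            lr = max(2.0 * (fit.partial_loglik - ll0), 0.0)
            out.adj_p = float(stats.chi2.sf(lr, k))
            out.adj_hr = fit.hazard_ratios[:k]
            out.converged = fit.converged and not fit.monotone_likelihood
        else:
            raise UndefinedInputError("log-rank branch has no adjusted refit")
        out.adjusted = True
    except UndefinedInputError:
        raise
    except Exception as exc:
        out.error = f"{type(exc).__name__}: {exc}"
        out.adjusted = False
    return out


def scan_results_frame(results):
    """ScanResult list -> tidy DataFrame (one row per SNP x model)."""
    import pandas as pd

    def fmt(arr):
        return "" if arr is None else ";".join(f"{v:.6g}" for v in np.atleast_1d(arr))

    rows = []
    for r in results:
        rows.append(
            {
                "snp_id": r.snp_id,
                "model": r.model,
                "method": r.method,
                "n_used": r.n_used,
                "n_events": r.n_events,
                "genotype_freq": r.genotype_freq,
                "plateaus": fmt(r.routing.plateaus if r.routing else None),
                "or": fmt(r.or_est),
                "hr": fmt(r.hr_est),
                "p_value": r.p_value,
                "significant": r.significant,
                "validity": r.validity,
                "validity_p": r.validity_p,
                "ph_p": r.ph_p,
                "adj_or": fmt(r.adj_or),
                "adj_hr": fmt(r.adj_hr),
                "adj_p": r.adj_p,
                "converged": r.converged,
                "error": r.error,
                "skip_reason": r.routing.skip_reason if r.routing else "",
            }
        )
    return pd.DataFrame(rows)
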