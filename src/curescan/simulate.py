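"""Synthetic cohort generation with cure-mixture outcome structure.

The generator emulates a stage I-III, MSI-L/MSS colorectal-cancer cohort:
HWE genotypes at specified minor-allele frequencies, baseline covariates
drawn from the reference cohort's marginal frequencies, and outcomes from
the same mixture structure the analysis assumes — a logistic incidence
submodel decides who is susceptible to metastasis, a Weibull
proportional-hazards latency submodel draws event times for the
susceptible, and everyone is subject to accrual-driven administrative
censoring. Cured patients are always censored.

Defaults are calibrated to the cohort the package's reference data
describe: n = 379, susceptibility probability 0.29 (long-term
metastasis-free plateau 0.71), ~21% observed events, follow-up capped at
10.9 years. The latency baseline (Weibull shape 1.2, scale ~2.5 years)
places ~90% of susceptible events within 5 years of diagnosis, mimicking
the early-metastasis pattern of colorectal cancer.

The latent truth (cure status, true event time) is carried alongside the
observed data for use by tests only; analysis modules never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import MISSING, ClinicalRecord, GenotypeMatrix, SnpMeta

#: Marginal level frequencies of the baseline covariates in the reference
#: cohort (fractions; each covariate's levels sum to 1).
DEFAULT_COVARIATE_MARGINALS = {
    "sex": {"female": 0.367, "male": 0.633},
    "age_group": {"<=60": 0.414, "60-70": 0.406, ">70": 0.179},
    "familial_risk": {"low": 0.517, "intermediate/high": 0.483},
    "treatment_5fu": {"5-FU": 0.565, "other/none": 0.420, "unknown": 0.016},
    "stage": {"I": 0.214, "II": 0.417, "III": 0.369},
    "location": {"colon": 0.615, "rectum": 0.385},
    "histology": {"non-mucinous": 0.905, "mucinous": 0.095},
    "vascular_invasion": {"absence": 0.639, "presence": 0.293, "unknown": 0.069},
    "lymphatic_invasion": {"absence": 0.625, "presence": 0.306, "unknown": 0.069},
    "braf_v600e": {"absence": 0.879, "presence": 0.050, "unknown": 0.071},
}

#: logit of the default susceptibility probability 0.29 (plateau 0.71)
DEFAULT_INCIDENCE_INTERCEPT = float(np.log(0.29 / 0.71))


@dataclass
class SnpEffect:
    """Planted effect of one SNP on incidence and/or latency.

    ``model`` chooses the encoding through which the effect acts:
    additive (allele count), dominant (any minor allele) or recessive
    (minor-homozygote).
    """

    snp: int = 0
    model: str = "additive"
    incidence_log_or: float = 0.0
    latency_log_hr: float = 0.0


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the study-condition calibration."""

    n: int = 379
    maf_list: tuple = (0.40,)
    genotype_missing_rate: float = 0.0
    covariate_marginals: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    incidence_intercept: float = DEFAULT_INCIDENCE_INTERCEPT
    snp_effects: tuple = ()
    #: covariate -> level -> log-OR added to the incidence linear predictor
    incidence_cov_effects: dict = field(default_factory=dict)
    #: covariate -> level -> log-HR added to the latency linear predictor
    latency_cov_effects: dict = field(default_factory=dict)
    weibull_shape: float = 1.2
    weibull_scale: float = 2.49
    accrual_years: float = 10.9
    horizon_years: float = 10.9
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(not 0.0 <= m <= 0.5 for m in self.maf_list):
            raise ValueError("MAFs must lie in [0, 0.5]")
        if not 0.0 <= self.genotype_missing_rate < 1.0:
            raise ValueError("missing rate must lie in [0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("follow-up horizon must be positive")
        for cov, levels in self.covariate_marginals.items():
            tot = sum(levels.values())
            # printed percentages round to 0.1%, so allow that much slack;
            # draws renormalize exactly
            if abs(tot - 1.0) > 5e-3:
                raise ValueError(f"{cov}: level frequencies sum to {tot}, not 1")


@dataclass
class SyntheticCohort:
    """Observed data plus the latent truth (test-only) and the spec echo."""

    genotypes: GenotypeMatrix
    clinical: list
    covariates: pd.DataFrame
    truth: pd.DataFrame  # susceptible, true_event_time, censor_time per patient
    spec: CohortSpec

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_years for r in self.clinical])

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.clinical])


def simulate_genotypes(
    n, maf_list, missing_rate=0.0, seed=None, rng=None, ld_copies=()
) -> GenotypeMatrix:
    """Independent HWE genotypes: codes ~ Binomial(2, MAF), MCAR missingness.

    ``ld_copies`` optionally appends linked SNPs: each ``(source_index,
    flip_prob)`` pair adds one SNP copying the source's genotypes, with each
    patient's genotype independently redrawn from the source's HWE
    distribution with probability ``flip_prob`` — flip_prob 0 gives complete
    LD (r^2 = 1), small values give the near-complete LD regime.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    maf = np.asarray(maf_list, float)
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("MAFs must lie in [0, 0.5]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    codes = rng.binomial(2, maf[:, None], size=(maf.size, n)).astype(np.int8)
    rows = [codes]
    for src, flip_prob in ld_copies:
        copy = codes[src].copy()
        redraw = rng.random(n) < flip_prob
        copy[redraw] = rng.binomial(2, maf[src], size=int(redraw.sum())).astype(np.int8)
        rows.append(copy[None, :])
    codes = np.vstack(rows)
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = MISSING
    snps = [
        SnpMeta(f"snp{i:05d}", str(1 + i % 22), 10_000 + 1_000 * i, "A", "G")
        for i in range(codes.shape[0])
    ]
    patients = [f"P{j:04d}" for j in range(n)]
    return GenotypeMatrix(snps, patients, codes)


def simulate_covariates(n, marginals=None, seed=None, rng=None) -> pd.DataFrame:
    """Draw categorical baseline covariates independently from marginals."""
    rng = np.random.default_rng(seed) if rng is None else rng
    marginals = DEFAULT_COVARIATE_MARGINALS if marginals is None else marginals
    out = {}
    for cov, levels in marginals.items():
        names = list(levels)
        probs = np.array([levels[k] for k in names], float)
        probs = probs / probs.sum()
        out[cov] = rng.choice(names, size=n, p=probs)
    return pd.DataFrame(out)


def _encode_effect(codes: np.ndarray, model: str) -> np.ndarray:
    x = codes.astype(float)
    x[codes == MISSING] = np.nan
    if model == "additive":
        return x
    if model == "dominant":
        return (x >= 1).astype(float)
    if model == "recessive":
        return (x == 2).astype(float)
    raise ValueError(f"unknown effect model {model!r}")


def _linear_predictors(genotypes, covariates, spec):
    """Incidence and latency linear predictors from planted effects."""
    n = covariates.shape[0]
    eta_inc = np.full(n, spec.incidence_intercept)
    eta_lat = np.zeros(n)
    for eff in spec.snp_effects:
        x = _encode_effect(genotypes.codes[eff.snp], eff.model)
        x = np.nan_to_num(x, nan=0.0)  # missing genotypes carry no effect
        eta_inc = eta_inc + eff.incidence_log_or * x
        eta_lat = eta_lat + eff.latency_log_hr * x
    for cov, levels in spec.incidence_cov_effects.items():
        for level, beta in levels.items():
            eta_inc = eta_inc + beta * (covariates[cov].to_numpy() == level)
    for cov, levels in spec.latency_cov_effects.items():
        for level, beta in levels.items():
            eta_lat = eta_lat + beta * (covariates[cov].to_numpy() == level)
    return eta_inc, eta_lat


def simulate_outcomes(genotypes, covariates, spec: CohortSpec, seed=None, rng=None):
    """Draw cure status, event times and censoring; returns a SyntheticCohort.

    Susceptibility ~ Bernoulli(expit(incidence predictor)); susceptible event
    times are Weibull PH with the latency predictor; censoring is the minimum
    of an accrual-driven administrative time (horizon - U(0, accrual)) and an
    optional exponential dropout. Cured patients are censored at their
    censoring time — never events.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed) if rng is None else rng
    n = covariates.shape[0]
    eta_inc, eta_lat = _linear_predictors(genotypes, covariates, spec)
    pi = 1.0 / (1.0 + np.exp(-np.clip(eta_inc, -30, 30)))
    susceptible = rng.random(n) < pi

    u = rng.random(n)
    true_t = spec.weibull_scale * (-np.log(u) / np.exp(eta_lat)) ** (1.0 / spec.weibull_shape)
    admin = spec.horizon_years - rng.uniform(0.0, spec.accrual_years, n)
    if spec.dropout_rate > 0:
        admin = np.minimum(admin, rng.exponential(1.0 / spec.dropout_rate, n))
    censor = np.maximum(admin, 1e-3)

    obs_t = np.where(susceptible, np.minimum(true_t, censor), censor)
    obs_e = (susceptible & (true_t <= censor)).astype(int)

    clinical = []
    for j, pid in enumerate(genotypes.patients):
        fields = {c: covariates.at[j, c] for c in covariates.columns if c != "stage"}
        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                stage=covariates.at[j, "stage"] if "stage" in covariates else "II",
                msi_status="MSS",
                time_years=float(obs_t[j]),
                event=int(obs_e[j]),
                **{k: v for k, v in fields.items() if k in ClinicalRecord.__dataclass_fields__},
            )
        )
    truth = pd.DataFrame(
        {
            "patient_id": genotypes.patients,
            "susceptible": susceptible,
            "true_event_time": np.where(susceptible, true_t, np.inf),
            "censor_time": censor,
        }
    )
    return SyntheticCohort(genotypes, clinical, covariates, truth, spec)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """One call: genotypes + covariates + outcomes under a single seed."""
    rng = np.random.default_rng(spec.seed)
    genotypes = simulate_genotypes(
        spec.n, spec.maf_list, spec.genotype_missing_rate, rng=rng
    )
    covariates = simulate_covariates(spec.n, spec.covariate_marginals, rng=rng)
    return simulate_outcomes(genotypes, covariates, spec, rng=rng)


@dataclass
class RoutingFixture:
    """A constructed cohort with the branch its SNP must route to."""

    name: str
    cohort: SyntheticCohort
    model: str
    expected_method: str
    snp_index: int = 0


def _fixture_cohort(codes, times, events, seed) -> SyntheticCohort:
    n = len(times)
    snps = [SnpMeta("fx0", "1", 1000, "A", "G")]
    patients = [f"P{j:04d}" for j in range(n)]
    gm = GenotypeMatrix(snps, patients, np.asarray(codes, np.int8)[None, :])
    rng = np.random.default_rng(seed)
    cov = simulate_covariates(n, rng=rng)
    clinical = [
        ClinicalRecord(
            patient_id=patients[j],
            stage=cov.at[j, "stage"],
            msi_status="MSS",
            time_years=float(times[j]),
            event=int(events[j]),
        )
        for j in range(n)
    ]
    truth = pd.DataFrame(
        {
            "patient_id": patients,
            "susceptible": events.astype(bool),
            "true_event_time": np.where(events == 1, times, np.inf),
            "censor_time": np.where(events == 0, times, np.inf),
        }
    )
    return SyntheticCohort(gm, clinical, cov, truth, CohortSpec(n=n, seed=seed))


def routing_fixtures(seed: int = 0) -> list:
    """Adversarial fixtures exercising every routing branch.

    Returns RoutingFixture items: (i) a cure-structure SNP with crossing
    survival curves and all plateaus in (0, 1) -> mixture-cure; (ii) a SNP
    whose minor-homozygote group has only events, all within 2 years -> cox;
    (iii) a SNP with an event-free minor-homozygote group -> log-rank;
    (iv) a SNP with a single minor homozygote -> skipped for recessive and
    co-dominant.
    """
    rng = np.random.default_rng(seed)
    fixtures = []
    n = 379

    def base_outcomes(n_sub, plateau=0.71):
        """Mixture outcomes for the unexposed background group."""
        sus = rng.random(n_sub) < (1 - plateau)
        t_ev = 2.49 * (-np.log(rng.random(n_sub))) ** (1 / 1.2)
        cens = 10.9 - rng.uniform(0, 8.0, n_sub)
        t = np.where(sus, np.minimum(t_ev, cens), cens)
        e = (sus & (t_ev <= cens)).astype(int)
        return t, e

    # (i) crossing curves, plateaus in (0,1): exposed minor homozygotes have a
    # *higher* long-term metastasis-free fraction but much faster events.
    n_exp = 53
    codes = np.array([2] * n_exp + list(rng.binomial(1, 0.45, n - n_exp)), np.int8)
    t_bg, e_bg = base_outcomes(n - n_exp, plateau=0.71)
    sus = rng.random(n_exp) < 0.20
    t_ev = 0.45 * (-np.log(rng.random(n_exp))) ** (1 / 1.2)  # events inside ~2 y
    cens = 10.9 - rng.uniform(0, 8.0, n_exp)
    t_exp = np.where(sus, np.minimum(t_ev, cens), cens)
    e_exp = (sus & (t_ev <= cens)).astype(int)
    times = np.concatenate([t_exp, t_bg])
    events = np.concatenate([e_exp, e_bg])
    fixtures.append(
        RoutingFixture(
            "crossing-cure", _fixture_cohort(codes, times, events, seed), "recessive", "mixture-cure"
        )
    )

    # (ii) minor-homozygote group: every patient metastasizes within 2 years.
    n_exp = 12
    codes = np.array([2] * n_exp + list(rng.binomial(1, 0.30, n - n_exp)), np.int8)
    t_exp = rng.uniform(0.1, 2.0, n_exp)
    e_exp = np.ones(n_exp, int)
    t_bg, e_bg = base_outcomes(n - n_exp)
    times = np.concatenate([t_exp, t_bg])
    events = np.concatenate([e_exp, e_bg])
    fixtures.append(
        RoutingFixture(
            "all-events-cox", _fixture_cohort(codes, times, events, seed + 1), "recessive", "cox"
        )
    )

    # (iii) event-free minor-homozygote group.
    n_exp = 12
    codes = np.array([2] * n_exp + list(rng.binomial(1, 0.30, n - n_exp)), np.int8)
    t_exp = 10.9 - rng.uniform(0, 8.0, n_exp)
    e_exp = np.zeros(n_exp, int)
    t_bg, e_bg = base_outcomes(n - n_exp)
    times = np.concatenate([t_exp, t_bg])
    events = np.concatenate([e_exp, e_bg])
    fixtures.append(
        RoutingFixture(
            "event-free-logrank",
            _fixture_cohort(codes, times, events, seed + 2),
            "recessive",
            "log-rank",
        )
    )

    # (iv) a single minor homozygote: too small to analyze.
    codes = np.array([2] + list(rng.binomial(1, 0.25, n - 1)), np.int8)
    t_all, e_all = base_outcomes(n)
    fixtures.append(
        RoutingFixture(
            "singleton-skip", _fixture_cohort(codes, t_all, e_all, seed + 3), "recessive", "skipped"
        )
    )
    return fixtures
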