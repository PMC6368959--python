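# curescan

Genome-wide time-to-event association scanning for cohorts with a cured
fraction.

## The problem

In population-based cancer cohorts a large subgroup never experiences the
outcome of interest no matter how long the follow-up: for stage I–III
colorectal cancer with microsatellite-stable (MSS) or MSI-low tumors, the
metastasis-free Kaplan–Meier curve plateaus around 0.71 — roughly 71% of
patients are long-term metastasis-free survivors. A Cox proportional
hazards model mixes two different questions in that setting: *who* will
ever metastasize, and *how fast* the susceptible do. A genetic variant can
act on either (or both), and a variant whose effect makes survival curves
cross is invisible to Cox entirely.

`curescan` implements a per-SNP adaptive analysis for exactly this
situation. The population survival is modelled as a two-component mixture

```
S_pop(t | z, x) = 1 − π(z) + π(z) · S_u(t | x)
```

where `π(z) = expit(b'z)` is the probability of being susceptible
(**incidence**, logistic, reported as odds ratios) and `S_u(t | x)` is a
proportional-hazards survival among the susceptible (**latency**, reported
as hazard ratios). The semiparametric model — Cox latency with a weighted
Breslow baseline and the zero-tail constraint `S_u(t) = 0` past the last
event time — is fitted by EM, with the observed-data log-likelihood
guaranteed non-decreasing at every iteration.

Because not every SNP × genetic-model pair has the cure structure, each
pair is routed by the Kaplan–Meier long-term (plateau) estimates of its
genotype categories:

| plateaus of the genotype categories | method |
|---|---|
| all strictly inside (0, 1) | mixture cure model |
| some category at 0, none at 1 | Cox proportional hazards (+ PH score test) |
| some category event-free (at 1) | log-rank test |
| any category with < 2 patients | skipped |

Four genetic encodings are scanned per SNP — additive, dominant, recessive
and co-dominant (which nests the other three, enabling likelihood-ratio
checks of the identified model) — with Bonferroni control at
`alpha / #SNPs`, data-driven baseline-covariate selection (univariable
screen at p < 0.10, backward elimination at p < 0.05, forced-in treatment
variable), and multivariable refits of the significant, plausible hits.

A calibrated synthetic-cohort generator (HWE genotypes, reference-cohort
covariate marginals, Weibull latency, accrual-driven censoring) makes the
whole pipeline testable end to end without patient-level registry data.

## Worked example

Fit the mixture cure model to a simulated cohort of 1,500 patients with a
planted dominant SNP (odds ratio 2 for being susceptible, hazard ratio 3
among the susceptible) — `examples/03_fit_mixture_cure.py`:

```
EM iterations: 16, converged: True
observed log-likelihood: -3803.41
component      name  estimate scale  ci_low  ci_high     p
incidence intercept     0.443    OR   0.365    0.525 0.000
incidence   carrier     1.669    OR   1.262    2.014 0.000
  latency   carrier     2.939    HR   2.404    3.669 0.000
baseline cure fraction (non-carriers): 0.693
```

Carriers have ~1.7× the odds of ever metastasizing (true value 2, inside
the bootstrap CI) and metastasize ~2.9× faster when susceptible (true
value 3); about 69% of non-carriers are long-term metastasis-free. The
other scripts in `examples/` walk through cohort simulation, SNP QC,
plateau-based routing of a small scan, and per-family covariate selection.

A shell interface wraps the same library calls:

```bash
curescan simulate --n 379 --seed 7 --out sim/
curescan run --genotypes sim/genotypes.tsv --clinical sim/clinical.csv \
             --out scan/ --covariates auto --forced treatment_5fu
curescan select-covariates --clinical sim/clinical.csv --family mixture-cure \
             --forced treatment_5fu --out sel/
```

`run` writes `scan_results.tsv` (one row per SNP × model), a routing
summary, the QC report and a YAML log of every threshold and seed.

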