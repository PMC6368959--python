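# Methods

## Model

The analysis targets cohorts in which a sizeable fraction of patients never
experiences the event (long-term metastasis-free survivors). Population
survival is a two-component mixture

S_pop(t | z, x) = 1 − π(z) + π(z) · S_u(t | x),

with a logistic **incidence** submodel π(z) = expit(b′z) for the
probability of being susceptible, and a **latency** submodel S_u(t | x) for
time-to-event among the susceptible. Incidence effects are reported as odds
ratios, latency effects as hazard ratios — deliberately separating "does
this factor change who metastasizes" from "does it change how fast".

The default latency is semiparametric proportional hazards:
S_u(t | x) = S_0(t)^exp(β′x) with a discrete baseline estimated by the
weighted Breslow estimator at the distinct event times, and the
**zero-tail constraint** S_u(t) = 0 for t beyond the largest event time.
The zero tail is what identifies the cured fraction in the semiparametric
fit: censored subjects past the last event are then cured with posterior
probability one. A parametric Weibull latency is available as a
cross-check; it does not need the zero-tail device.

### EM algorithm

Susceptibility is a latent class for censored subjects. The E-step computes
posterior susceptibility weights

w_i = 1 (event), w_i = π_i S_u(t_i) / (1 − π_i + π_i S_u(t_i)) (censored);

the M-step maximizes the expected complete-data log-likelihood: a logistic
IRLS of the fractional weights on z, and a case-weighted Cox partial
likelihood for β (subjects enter risk sets with weight w_i; w_i = 0 leaves
the risk set) followed by the weighted Breslow baseline update.

Numerical choices that matter:

* **Breslow tie convention inside the EM.** The weighted Breslow partial
  likelihood is the exact profile of the complete-data objective over the
  discrete baseline, so maximizing it plus updating the baseline is a true
  (generalized) EM step and the observed-data log-likelihood is
  non-decreasing — the fitter asserts this at every iteration. The Efron
  convention is *not* that profile, and under tied event times (which
  bootstrap resampling always creates) it can break monotonicity. The
  public `cox_fit` keeps Efron as its default for ordinary Cox analyses;
  only the EM's internal latency update is Breslow.
* **One damped Newton step per M-step** (ECM). With step-halving this still
  increases the partial likelihood, preserves the EM fixed point, and
  roughly halves the cost of a fit; the test suite verifies the fast path
  agrees with fully-converged inner maximization to optimizer tolerance.
  Logistic IRLS steps are also step-halved: full IRLS steps can overshoot
  near separation, which would violate ascent.
* **Separation** in either component is handled by capping |coefficient| at
  15 with a flag on the fit, never by silent divergence. A cohort with no
  censored subject at or past the last event time cannot identify the cure
  fraction; the fit carries an identifiability warning.
* **Convergence**: absolute change in observed log-likelihood < 1e-6, or
  500 iterations; non-convergence is recorded on the fit and propagated to
  scan output rather than raised.

### Inference

Bootstrap is the default for reported cure-model fits: patients are
resampled with replacement, the EM refitted, percentile 2.5/97.5 CIs taken;
p-values are Wald with the bootstrap SE; everything is seedable and
bit-reproducible. The semiparametric baseline makes the analytic
information matrix unreliable, which is why a numeric-Hessian Wald option
is offered only for the parametric (Weibull) latency. Whether the original
analysis used bootstrap, Wald or profile intervals is not documented;
bootstrap is the package's choice.

Inside the genome-wide scan, bootstrap per SNP × model is computationally
out of the question, so the scan's cure-branch p-values are
likelihood-ratio tests against the intercept-only cure model (the null fit
is shared across all SNPs with the same missingness pattern, and the
alternative is warm-started from it). The LR and Wald tests are
asymptotically equivalent; the LR version is deterministic and calibrated
(see the null-scan simulation below).

## Routing

For each SNP × genetic model the Kaplan–Meier long-term (plateau) estimate
— KM survival at the category's own last follow-up — is computed for each
genotype category of that encoding: the two collapsed groups for
dominant/recessive, the three raw genotypes for co-dominant *and* additive
(a 1-df trend cannot be routed on collapsed categories). Routing rules:
every plateau in (0, 1) → mixture cure; any event-free category → log-rank
(taking precedence, since neither survival model is then fitted); else a
zero-plateau category → Cox. Categories with fewer than 2 patients make
the pair unanalyzable (skipped). The proportional-hazards score test
(Grambsch–Therneau scaled-Schoenfeld form, KM time transform by default)
is run on Cox-branch hits at α = 0.05.

Genetic-model validity of a significant additive/dominant/recessive hit is
a likelihood-ratio test against the co-dominant fit on the same patients
under the same method branch (observed-data likelihood for the cure
branch, partial likelihood for Cox), df = the parameter-count difference,
α = 0.05 (configurable; the validity α is not documented in the reference
analysis). When the co-dominant design collapses onto the identified model
(e.g. no minor homozygotes), the LR statistic is zero and the model
stands.

## Covariate selection

Separately per model family: univariable screen at p < 0.10, backward
elimination at p < 0.05, forced-in variables never removed. Multi-level
covariates are tested jointly (one dummy per non-reference level) with
likelihood-ratio tests; for the cure family a variable's p is the smaller
of its incidence-drop and latency-drop LR p-values — a covariate is kept
if it matters in either component ("either" vs "both" is configurable in
principle; "either" is the default because a cured-fraction confounder
must be adjustable even when it carries no timing signal). Joint Wald
tests would be the textbook alternative; LR was chosen because the
semiparametric cure fit has no cheap reliable Wald covariance (see above)
and LR keeps the selection trace deterministic. Ties in the removal step
break toward the variable later in the user-specified order.

Patients with an unknown level of any covariate in the model are excluded
(complete-case), so the adjusted n drops relative to the univariable scan.

## Multiple testing

Bonferroni divides α by the **number of SNPs** (with the reference
post-QC count of 810,622 SNPs and α = 0.05 this is 6.2 × 10⁻⁸), not by
SNP × model pairs — matching the reference analysis. Null simulation at
reduced scale (scans of 100 SNPs at n = 379, 40,000 null p-values per
genetic model) shows the scan's p-values are calibrated to three digits at
conventional levels (P(p < 0.05) ≈ 0.050, P(p < 0.01) ≈ 0.010–0.012). In
the extreme tail that Bonferroni actually uses (5 × 10⁻⁴ at this scale)
the additive trend is slightly conservative (~0.7 × nominal) while the
dominant/recessive/co-dominant encodings are mildly anti-conservative
(~1.2–1.9 × nominal) — ordinary small-sample behavior of the asymptotic
chi-square reference with ~80 events. Consequently the per-model
family-wise error over 200 null scans sits between ~0.035 and ~0.085,
inside or at the edge of the binomial region around α; the co-dominant
encoding (4 df, smallest genotype cells) is the boundary case. Pooling
hits over all four encodings inflates the realized family-wise error
further, to roughly 2–3 × α, because the per-SNP multiplicity over four
correlated encodings is not corrected. Both effects are properties of the
design being replicated, not of the implementation; users wanting strict
control should divide by 4 × #SNPs (the `n_tests` argument makes this a
one-line change).

## Synthetic cohorts

The generator emulates the reference cohort: n = 379 stage I–III MSI-L/MSS
colorectal-cancer patients. Genotypes are independent HWE draws at given
MAFs with MCAR missingness. Covariate marginals default to the packaged
baseline table (e.g. 36.7% female; stage I/II/III = 21.4/41.7/36.9%).
Outcomes: susceptibility Bernoulli with intercept logit(0.29) (cure
fraction 0.71); susceptible event times Weibull PH with shape 1.2 and
scale 2.49 years, placing ~90% of susceptible events within 5 years of
diagnosis (the early-metastasis pattern of colorectal cancer); censoring
administrative, horizon 10.9 years minus a uniform accrual offset over the
full window. Under these defaults simulated cohorts show ~21–23% observed
events and a KM plateau of ~0.71, matching the reference cohort's printed
21% and 0.71. SNP and covariate effects enter the incidence and/or latency
linear predictors through a chosen encoding; confounding scenarios are
built by wiring a covariate into both the genotype frequencies and the
outcome predictors.

What the generator does **not** emulate: genome-wide LD structure (an
optional copy-with-flip-noise mode covers the r² tests only), population
stratification, genotyping batch effects, informative censoring, and
covariate correlations (covariates are drawn independently unless a
scenario wires them together). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generating
model, not robustness to those real-data complications.

## Problem sizes

The simulation-based checks use sizes chosen for single-core desk runs:
parameter recovery at n = 2,000 × 200 replicates; PH-test type-I error at
n = 200 × 1,000 replicates; the null scan at 100 SNPs × 200 replicates,
n = 379; bootstrap coverage at n = 120 with 60 resamples. These match the
precision needed for the tolerances asserted (median bias within 10%,
rejection rates within a few points of nominal).

## Known limitations

* LD r² is the genotype-correlation (composite) definition, not the
  EM-haplotype definition; they agree in the near-complete-LD regime the
  package reports on.
* The exact HWE test conditions on allele counts without a mid-p
  correction; it is conservative at small minor-allele counts.
* The Cox engine handles right censoring only — no time-varying
  covariates, frailty, left truncation or interval censoring.
* Cure-model p-values in the scan are asymptotic LR; for genotype
  categories with very few patients the chi-square approximation in the
  extreme tail is untested at desk scale beyond the calibration simulation
  described above.
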