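"""Generate a synthetic stage I-III MSI-L/MSS-like cohort and inspect it.

The generator draws HWE genotypes, baseline covariates with the reference
cohort's marginal frequencies, and mixture outcomes: ~29% of patients are
susceptible to metastasis, the rest are long-term metastasis-free.
"""

import numpy as np

from curescan import CohortSpec, kaplan_meier, long_term_estimate, simulate_cohort

cohort = simulate_cohort(CohortSpec(n=379, maf_list=(0.40, 0.25), seed=1))

events = cohort.events
km = kaplan_meier(cohort.times, events)
print(f"patients:              {cohort.spec.n}")
print(f"observed metastases:   {events.sum()}  ({100 * events.mean():.1f}%)")
print(f"longest follow-up:     {cohort.times.max():.1f} years")
print(f"KM long-term plateau:  {long_term_estimate(km):.3f}")
print(f"true cured fraction:   {1 - cohort.truth['susceptible'].mean():.3f}")

# The plateau estimates the cured fraction: a value near 0.71 says ~71% of
# the cohort will never metastasize, which is what makes a plain Cox model
# the wrong default and the mixture cure model the right one.
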