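"""Reference cohort constants and the baseline-characteristics table.

The reference cohort is a population-based series of 379 stage I-III
colorectal-cancer patients with MSI-L/MSS tumors: 81 metastases (21%)
within a follow-up capped at 10.9 years, and a long-term metastasis-free
Kaplan-Meier plateau of 0.71. The packaged CSV carries the published
baseline characteristics (counts and percentages per covariate level,
with per-level metastasis counts); the simulator's default covariate
marginals are derived from it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: analysis cohort size after exclusions
COHORT_N = 379
#: observed metastases in the reference cohort
COHORT_EVENTS = 81
#: long-term metastasis-free survival plateau
COHORT_PLATEAU = 0.71
#: largest follow-up time, years
COHORT_MAX_FOLLOWUP = 10.9
#: SNPs passing QC in the reference genome-wide scan
REFERENCE_N_SNPS = 810_622


def baseline_table() -> pd.DataFrame:
    """The reference cohort's baseline characteristics table.

    Columns: variable, level, n_patients, pct_total (printed % of the
    cohort), n_metastasis, pct_metastasis (printed % within the level).
    """
    with resources.files("curescan.data").joinpath(
        "reference_cohort_baseline.csv"
    ).open() as fh:
        return pd.read_csv(fh)
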