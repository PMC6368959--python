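import numpy as np
import pytest

from curescan.simulate import CohortSpec, SnpEffect, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A single seeded cohort under the default study-condition calibration."""
    return simulate_cohort(CohortSpec(seed=20260929))


@pytest.fixture(scope="session")
def effect_cohort():
    """n=2000 cohort with a dominant SNP acting on both components."""
    spec = CohortSpec(
        n=2000,
        maf_list=(0.3,),
        seed=77,
        snp_effects=(SnpEffect(0, "dominant", np.log(2.0), np.log(3.0)),),
    )
    return simulate_cohort(spec)


def km_by_hand(times, events):
    """Independent product-limit oracle: naive loop over sorted times."""
    order = np.argsort(times)
    t, e = np.asarray(times, float)[order], np.asarray(events, int)[order]
    s = 1.0
    out_t, out_s = [], []
    i, n = 0, len(t)
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += e[j]
            j += 1
        if d > 0:
            at_risk = n - i
            s *= 1.0 - d / at_risk
            out_t.append(t[i])
            out_s.append(s)
        i = j
    return np.array(out_t), np.array(out_s)
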