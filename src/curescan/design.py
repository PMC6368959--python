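"""Design-matrix construction for categorical baseline covariates.

Multi-level covariates are dummy-coded against their most frequent level.
Patients with an ``unknown`` level in any requested covariate are excluded
(complete-case), mirroring how adjusted survival analyses handle missing
baseline data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import COVARIATE_FIELDS


def clinical_frame(records) -> pd.DataFrame:
    """ClinicalRecord list -> DataFrame (one row per patient)."""
    cols = ["patient_id", "stage", "msi_status", *COVARIATE_FIELDS, "time_years", "event"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def categorical_design(
    frame: pd.DataFrame, covariates, drop_unknown: bool = True
) -> tuple[np.ndarray, list, np.ndarray]:
    """Dummy-code the requested covariates.

    Returns (design, column names, complete-case mask over input rows).
    Reference level per covariate = its most frequent non-unknown level;
    constant covariates contribute no columns.
    """
    n = len(frame)
    mask = np.ones(n, dtype=bool)
    if drop_unknown:
        for cov in covariates:
            mask &= frame[cov].to_numpy() != "unknown"
    cols, names = [], []
    sub = frame.loc[mask]
    for cov in covariates:
        values = sub[cov].astype(str)
        levels = values.value_counts().index.tolist()
        if len(levels) < 2:
            continue  # constant after exclusions: nothing to encode
        for level in levels[1:]:  # reference = most frequent
            cols.append((values == level).to_numpy(float))
            names.append(f"{cov}[{level}]")
    design = np.column_stack(cols) if cols else np.empty((mask.sum(), 0))
    return design, names, mask


def covariate_groups(names) -> dict:
    """Map covariate -> column indices in a dummy design built above."""
    groups: dict = {}
    for i, nm in enumerate(names):
        cov = nm.split("[", 1)[0]
        groups.setdefault(cov, []).append(i)
    return groups
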