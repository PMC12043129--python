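"""Shared regression-design construction for the cohort table.

One encoding, used by both the outcome generator and the estimator, so that
truth coefficients and fitted coefficients live on the same columns:

* ``sex_female`` — binary indicator (male is the reference)
* ``bw_c`` — birth weight in kg, centered at 3.1 kg
* ``age_c`` — child age in months, centered at 44 months
* ``edu_primary``/``edu_ordinary``/``edu_tertiary`` — maternal education
  dummies (no formal education is the reference)
* ``ses_moderate``/``ses_low`` — SES category dummies (high is the reference)

Centering the continuous covariates keeps the intercept on the scale of the
baseline outcome prevalence, which is how the synthetic truths are specified.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

BW_CENTER_KG = 3.1
AGE_CENTER_MONTHS = 44.0

EDUCATION_LEVELS = ("none", "primary", "ordinary", "tertiary")
SES_LEVELS = ("high", "moderate", "low")

#: Covariate set retained by the study's stepwise selection (the default
#: adjustment set): child sex, birth weight, maternal education, child age
#: and household SES.
DEFAULT_COVARIATES = (
    "sex_female",
    "birth_weight_kg",
    "maternal_education",
    "age_months",
    "ses_category",
)


def encode_covariates(
    cohort: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Expand raw covariate columns into the model encoding above."""
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "sex_female":
            cols["sex_female"] = cohort["sex_female"].to_numpy(dtype=float)
        elif cov == "birth_weight_kg":
            cols["bw_c"] = cohort["birth_weight_kg"].to_numpy(dtype=float) - BW_CENTER_KG
        elif cov == "age_months":
            cols["age_c"] = cohort["age_months"].to_numpy(dtype=float) - AGE_CENTER_MONTHS
        elif cov == "maternal_education":
            edu = cohort["maternal_education"].astype(str)
            unknown = set(edu.unique()) - set(EDUCATION_LEVELS)
            if unknown:
                raise ValueError(f"unknown maternal_education levels: {sorted(unknown)}")
            for lvl in EDUCATION_LEVELS[1:]:
                cols[f"edu_{lvl}"] = (edu == lvl).to_numpy(dtype=float)
        elif cov == "ses_category":
            ses = cohort["ses_category"].astype(str)
            unknown = set(ses.unique()) - set(SES_LEVELS)
            if unknown:
                raise ValueError(f"unknown ses_category levels: {sorted(unknown)}")
            for lvl in SES_LEVELS[1:]:
                cols[f"ses_{lvl}"] = (ses == lvl).to_numpy(dtype=float)
        elif cov in cohort.columns:
            # numeric passthrough for user-defined covariates
            cols[cov] = cohort[cov].to_numpy(dtype=float)
        else:
            raise KeyError(f"cohort table lacks covariate column {cov!r}")
    return pd.DataFrame(cols, index=cohort.index)


def build_design(
    quantized_scores: pd.DataFrame,
    covariate_design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full design matrix: intercept, quantile scores, encoded covariates."""
    parts = [pd.Series(1.0, index=quantized_scores.index, name="const"),
             quantized_scores.astype(float)]
    if covariate_design is not None and covariate_design.shape[1] > 0:
        parts.append(covariate_design.astype(float))
    return pd.concat(parts, axis=1)
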