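"""Covariate coding shared by the simulator and the models.

Conventions:

* ``age`` — age in decades centred at 85 years, ``(age_years - 85) / 10``;
* ``care_level`` — the 1–12 care-dependency score, used as a numeric score;
* ``cps`` — cognitive performance scale 0–6, numeric score;
* ``depression`` — indicator for DRS >= 3 (the instrument's own clinical
  threshold for evidence of minor to major depression);
* ``female`` — indicator for female sex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DRS_DEPRESSION_CUT = 3

#: covariates understood by ``code_covariates`` / model risk sets
KNOWN_COVARIATES = ("age", "care_level", "cps", "depression", "female")


def code_covariates(records: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Return the model-scale covariate columns ``names`` for ``records``.

    ``records`` must carry the raw columns each coded covariate derives from
    (``age`` or ``birth_year``+``assessment_year``, ``sex``, ``care_level``,
    ``cps``, ``drs``).
    """
    unknown = [n for n in names if n not in KNOWN_COVARIATES]
    if unknown:
        raise ValueError(
            f"unknown covariate(s) {unknown!r}; known: {list(KNOWN_COVARIATES)}"
        )
    out = {}
    for name in names:
        if name == "age":
            if "age" in records.columns:
                age = records["age"].to_numpy(dtype=float)
            else:
                age = (
                    records["assessment_year"] - records["birth_year"]
                ).to_numpy(dtype=float)
            out[name] = (age - 85.0) / 10.0
        elif name == "care_level":
            out[name] = records["care_level"].to_numpy(dtype=float)
        elif name == "cps":
            out[name] = records["cps"].to_numpy(dtype=float)
        elif name == "depression":
            out[name] = (
                records["drs"].to_numpy(dtype=float) >= DRS_DEPRESSION_CUT
            ).astype(float)
        elif name == "female":
            sex = records["sex"]
            if sex.dtype == object or isinstance(sex.dtype, pd.CategoricalDtype):
                out[name] = (sex == "female").to_numpy(dtype=float)
            else:
                out[name] = sex.to_numpy(dtype=float)
    return pd.DataFrame(out, index=records.index)


def linear_predictor(
    records: pd.DataFrame, coefficients: dict[str, float]
) -> np.ndarray:
    """Xβ on the logit scale for coefficient map ``coefficients``."""
    if not coefficients:
        return np.zeros(len(records))
    coded = code_covariates(records, list(coefficients))
    beta = np.array([coefficients[c] for c in coded.columns])
    return coded.to_numpy() @ beta
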