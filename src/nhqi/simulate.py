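"""Synthetic resident populations with known facility-level variance.

Two generators are provided:

* :func:`simulate_outcomes` draws a binary outcome directly from the
  random-intercept logistic model (facility intercepts ~ N(0, group_sd²) on
  the logit scale).  It is the workhorse for parameter-recovery and
  calibration studies because the data-generating model coincides exactly
  with the fitted model.
* :func:`simulate_items` draws the full raw item schema (medication counts,
  pain frequency/intensity, restraint use and consent context, weight-loss
  flags, exclusion items) so the indicator-construction rules can be
  exercised end to end.  Per-indicator latent prevalences are steered to the
  configured targets by solving for the intercept that yields the requested
  population-average rate under the configured facility variance.

Randomness uses a single root seed with named derived streams (facility
effects, covariates, outcomes, item noise, missingness), so adding a stream
never shifts the draws of existing ones.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from nhqi.coding import KNOWN_COVARIATES, linear_predictor

INDICATOR_IDS = (
    "polypharmacy",
    "pain_self",
    "pain_observed",
    "restraint_trunk",
    "restraint_bedrails",
    "weight_loss",
)

PAIN_FREQ_LEVELS = ("none", "nondaily", "daily")
PAIN_INTENSITY_LEVELS = (
    "none",
    "mild",
    "moderate",
    "strong",
    "very_strong_unbearable",
)
RESTRAINT_CONTEXTS = ("none", "capable_agreed", "incapable", "not_clarified")

# fixed stream ids: append-only so existing draws never shift
_STREAMS = {
    "facility_sizes": 0,
    "covariates": 1,
    "outcome_effects": 2,
    "outcomes": 3,
    "items:polypharmacy": 10,
    "items:pain_self": 11,
    "items:pain_observed": 12,
    "items:restraint_trunk": 13,
    "items:restraint_bedrails": 14,
    "items:weight_loss": 15,
    "effects:polypharmacy": 20,
    "effects:pain_self": 21,
    "effects:pain_observed": 22,
    "effects:restraint_trunk": 23,
    "effects:restraint_bedrails": 24,
    "effects:weight_loss": 25,
    "missing:pain_self": 30,
    "missing:pain_observed": 31,
    "missing:restraint_bedrails": 32,
    "missing:weight_loss": 33,
    "exclusions": 40,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


def _discretized_normal(levels: np.ndarray, mean: float, sd: float) -> list[float]:
    w = np.exp(-0.5 * ((levels - mean) / sd) ** 2)
    return list(w / w.sum())


class CovariateParams(BaseModel):
    """Distributional parameters for the resident case-mix covariates."""

    age_mean: float = 86.1
    age_sd: float = Field(8.36, gt=0)
    age_min: float = 65.0
    age_max: float = 110.0
    p_female: float = Field(0.728, ge=0, le=1)
    # care level 1-12, median near 6
    care_level_probs: list[float] = Field(
        default_factory=lambda: _discretized_normal(np.arange(1, 13), 6.3, 2.8)
    )
    # CPS 0-6, mildly right-skewed
    cps_probs: list[float] = Field(
        default_factory=lambda: [0.22, 0.16, 0.15, 0.19, 0.13, 0.09, 0.06]
    )
    # DRS 0-14, geometric-type decay; ~1/3 of residents at the >=3 cut
    drs_probs: list[float] = Field(
        default_factory=lambda: list(
            (w := 0.72 ** np.arange(15)) / w.sum()
        )
    )
    los_log_median: float = Field(default=float(np.log(859.0)))
    los_log_sd: float = Field(1.1, gt=0)

    @field_validator("care_level_probs", "cps_probs", "drs_probs")
    @classmethod
    def _probs_ok(cls, v):
        arr = np.asarray(v, dtype=float)
        if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-8):
            raise ValueError("probabilities must be >= 0 and sum to 1")
        return [float(x) for x in arr]

    @model_validator(mode="after")
    def _lengths(self):
        if len(self.care_level_probs) != 12:
            raise ValueError("care_level_probs must have 12 entries (levels 1-12)")
        if len(self.cps_probs) != 7:
            raise ValueError("cps_probs must have 7 entries (levels 0-6)")
        if len(self.drs_probs) != 15:
            raise ValueError("drs_probs must have 15 entries (levels 0-14)")
        return self


class ItemModel(BaseModel):
    """Latent model for one indicator in the item-level generator.

    ``prevalence`` is the target population-average outcome rate among
    eligible residents; ``group_sd`` the facility random-intercept SD on the
    logit scale (so the latent group variance is ``group_sd**2``);
    ``effects`` the logit-scale case-mix coefficients.
    """

    prevalence: float = Field(gt=0, lt=1)
    group_sd: float = Field(ge=0)
    effects: dict[str, float] = Field(default_factory=dict)

    @field_validator("effects")
    @classmethod
    def _known(cls, v):
        unknown = set(v) - set(KNOWN_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in effects: {sorted(unknown)}")
        return v


def _default_items() -> dict[str, ItemModel]:
    # prevalence targets from the national quality-indicator survey means;
    # group SDs chosen so the latent ICC1 matches the risk-adjusted estimates
    # reported for the Swiss sample (0.068 ... 0.396)
    def sd_for_icc1(icc: float) -> float:
        return float(np.sqrt(icc / (1 - icc) * (np.pi**2 / 3)))

    return {
        "polypharmacy": ItemModel(
            prevalence=0.430,
            group_sd=sd_for_icc1(0.068),
            effects={"cps": 0.10, "care_level": 0.08, "age": 0.10},
        ),
        "pain_self": ItemModel(
            prevalence=0.197,
            group_sd=sd_for_icc1(0.134),
            effects={"cps": -0.15, "care_level": 0.06, "depression": 0.50, "female": 0.20},
        ),
        "pain_observed": ItemModel(
            prevalence=0.149,
            group_sd=sd_for_icc1(0.223),
            effects={"cps": 0.10, "care_level": 0.06, "depression": 0.45, "female": 0.15},
        ),
        "restraint_trunk": ItemModel(
            prevalence=0.034,
            group_sd=sd_for_icc1(0.396),
            effects={"cps": 0.35, "care_level": 0.12},
        ),
        "restraint_bedrails": ItemModel(
            prevalence=0.130,
            group_sd=sd_for_icc1(0.371),
            effects={"cps": 0.30, "care_level": 0.10},
        ),
        "weight_loss": ItemModel(
            prevalence=0.079,
            group_sd=sd_for_icc1(0.137),
            effects={"cps": 0.10, "care_level": 0.08},
        ),
    }


class ExclusionParams(BaseModel):
    """Rates of the exclusion-relevant items in the item generator."""

    p_trunk_consented: float = Field(0.010, ge=0, le=1)
    p_bedrails_consented: float = Field(0.030, ge=0, le=1)
    p_life_expectancy_yes: float = Field(0.030, ge=0, le=1)
    p_life_expectancy_not_collected: float = Field(0.050, ge=0, le=1)
    p_admission_assessment: float = Field(0.050, ge=0, le=1)


class SimulationConfig(BaseModel):
    """Full configuration of the synthetic-population generators.

    Defaults emulate the national pilot sample: 152 facilities of ~75
    long-term residents, mean age 86.1 (SD 8.36), 72.8% female, care level
    median 6, and a 13.4% rate of invalid self-reported-pain answers.
    """

    n_facilities: int = Field(152, ge=1)
    residents_per_facility: Union[int, tuple[int, int]] = 75
    group_sd: float = Field(0.7, ge=0)
    intercept: float = -1.5
    fixed_effects: dict[str, float] = Field(default_factory=dict)
    covariate_params: CovariateParams = Field(default_factory=CovariateParams)
    items: dict[str, ItemModel] = Field(default_factory=_default_items)
    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "pain_self": 0.134,
            "pain_observed": 0.007,
            "restraint_bedrails": 0.016,
            "weight_loss": 0.001,
        }
    )
    exclusion_params: ExclusionParams = Field(default_factory=ExclusionParams)
    assessment_year: int = 2017
    seed: int = 0

    @field_validator("residents_per_facility")
    @classmethod
    def _rpf(cls, v):
        if isinstance(v, int):
            if v < 1:
                raise ValueError("residents_per_facility must be >= 1")
        else:
            lo, hi = v
            if lo < 1 or hi < lo:
                raise ValueError("range must satisfy 1 <= lo <= hi")
        return v

    @field_validator("fixed_effects")
    @classmethod
    def _fe(cls, v):
        unknown = set(v) - set(KNOWN_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in fixed_effects: {sorted(unknown)}")
        return v

    @field_validator("missingness_rates")
    @classmethod
    def _mr(cls, v):
        allowed = {"pain_self", "pain_observed", "restraint_bedrails", "weight_loss"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown missingness keys: {sorted(unknown)}")
        for key, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missingness rate for {key} not in [0,1]")
        return v

    @field_validator("items")
    @classmethod
    def _items(cls, v):
        unknown = set(v) - set(INDICATOR_IDS)
        if unknown:
            raise ValueError(f"unknown indicator ids in items: {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# covariate generation


def _facility_sizes(config: SimulationConfig) -> np.ndarray:
    rpf = config.residents_per_facility
    if isinstance(rpf, int):
        return np.full(config.n_facilities, rpf, dtype=int)
    rng = _rng(config.seed, "facility_sizes")
    lo, hi = rpf
    return rng.integers(lo, hi + 1, size=config.n_facilities)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Resident frame with facility ids and case-mix covariates only."""
    sizes = _facility_sizes(config)
    n = int(sizes.sum())
    width = max(3, len(str(config.n_facilities)))
    fac_labels = np.array(
        [f"F{i + 1:0{width}d}" for i in range(config.n_facilities)]
    )
    facility_id = np.repeat(fac_labels, sizes)
    within = np.concatenate([np.arange(1, s + 1) for s in sizes])
    resident_id = np.char.add(
        np.char.add(facility_id.astype(str), "-R"),
        np.char.zfill(within.astype(str), 4),
    )

    cp = config.covariate_params
    rng = _rng(config.seed, "covariates")
    a, b = (
        (cp.age_min - cp.age_mean) / cp.age_sd,
        (cp.age_max - cp.age_mean) / cp.age_sd,
    )
    age = truncnorm.rvs(a, b, loc=cp.age_mean, scale=cp.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < cp.p_female, "female", "male")
    care_level = rng.choice(np.arange(1, 13), size=n, p=cp.care_level_probs)
    cps = rng.choice(np.arange(7), size=n, p=cp.cps_probs)
    drs = rng.choice(np.arange(15), size=n, p=cp.drs_probs)
    los_days = np.exp(rng.normal(cp.los_log_median, cp.los_log_sd, size=n))
    los_days = np.clip(los_days, 1, 8000).astype(int)
    export_date = pd.Timestamp(config.assessment_year, 7, 1)
    admission = export_date - pd.to_timedelta(los_days, unit="D")

    return pd.DataFrame(
        {
            "facility_id": facility_id,
            "resident_id": resident_id,
            "birth_year": (config.assessment_year - np.round(age)).astype(int),
            "admission_date": admission.strftime("%Y-%m-%d"),
            "assessment_year": config.assessment_year,
            "age": age,
            "sex": sex,
            "care_level": care_level,
            "cps": cps,
            "drs": drs,
        }
    )


# ---------------------------------------------------------------------------
# outcome-level generator


def simulate_outcomes(
    config: SimulationConfig, risk_set: Optional[list[str]] = None
) -> pd.DataFrame:
    """Draw a binary outcome directly from the random-intercept logit model.

    ``risk_set`` names the covariates entering the linear predictor; each
    must have a coefficient in ``config.fixed_effects``.  The returned frame
    carries the raw covariates, the drawn ``outcome`` and the true
    ``facility_effect`` (latent logit-scale intercept) for diagnostics.
    """
    risk_set = list(risk_set or [])
    unknown = set(risk_set) - set(KNOWN_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariate(s) in risk_set: {sorted(unknown)}")
    missing = set(risk_set) - set(config.fixed_effects)
    if missing:
        raise ValueError(
            f"risk_set covariates without a coefficient in fixed_effects: {sorted(missing)}"
        )

    records = simulate_covariates(config)
    coefs = {c: config.fixed_effects[c] for c in risk_set}
    xb = linear_predictor(records, coefs)

    eff_rng = _rng(config.seed, "outcome_effects")
    b = eff_rng.normal(0.0, config.group_sd, size=config.n_facilities)
    codes = pd.factorize(records["facility_id"], sort=True)[0]
    eta = config.intercept + xb + b[codes]

    out_rng = _rng(config.seed, "outcomes")
    outcome = (out_rng.random(len(records)) < expit(eta)).astype(int)

    records = records.copy()
    records["facility_effect"] = b[codes]
    records["outcome"] = outcome
    return records


# ---------------------------------------------------------------------------
# item-level generator

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(31)


def _steered_intercept(xb: np.ndarray, group_sd: float, target: float) -> float:
    """Intercept giving population-average outcome rate ``target``.

    Averages the logistic over the N(0, group_sd²) facility effect by
    Gauss–Hermite quadrature and over the empirical covariate draw, then
    solves for the intercept by bisection.
    """
    shift = np.sqrt(2.0) * group_sd * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)

    def mean_rate(c: float) -> float:
        # n x q matrix collapsed over both axes
        return float(w @ expit(np.add.outer(shift, xb + c)).mean(axis=1)) - target

    lo = float(logit(target)) - 3 * group_sd - np.abs(xb).max() - 5
    hi = float(logit(target)) + 3 * group_sd + np.abs(xb).max() + 5
    return brentq(mean_rate, lo, hi, xtol=1e-10)


def _latent_outcome(
    config: SimulationConfig, records: pd.DataFrame, indicator: str
) -> np.ndarray:
    item = config.items[indicator]
    xb = linear_predictor(records, item.effects)
    c = _steered_intercept(xb, item.group_sd, item.prevalence)
    b = _rng(config.seed, f"effects:{indicator}").normal(
        0.0, item.group_sd, size=config.n_facilities
    )
    codes = pd.factorize(records["facility_id"], sort=True)[0]
    p = expit(c + xb + b[codes])
    rng = _rng(config.seed, f"items:{indicator}")
    return (rng.random(len(records)) < p).astype(int)


def _pain_items(y: np.ndarray, rng: np.random.Generator):
    """Map a latent pain outcome to (frequency, intensity) item pairs."""
    qualifying = [
        ("daily", "moderate", 0.55),
        ("daily", "strong", 0.25),
        ("daily", "very_strong_unbearable", 0.10),
        ("nondaily", "very_strong_unbearable", 0.10),
    ]
    non_qualifying = [
        ("none", "none", 0.70),
        ("nondaily", "mild", 0.12),
        ("nondaily", "moderate", 0.10),
        ("daily", "mild", 0.05),
        ("nondaily", "strong", 0.03),
    ]
    n = len(y)
    freq = np.empty(n, dtype=object)
    inten = np.empty(n, dtype=object)
    for value, combos in ((1, qualifying), (0, non_qualifying)):
        mask = y == value
        probs = np.array([c[2] for c in combos])
        idx = rng.choice(len(combos), size=int(mask.sum()), p=probs / probs.sum())
        freq[mask] = np.array([c[0] for c in combos], dtype=object)[idx]
        inten[mask] = np.array([c[1] for c in combos], dtype=object)[idx]
    return freq, inten


def simulate_items(config: SimulationConfig) -> pd.DataFrame:
    """Generate the full raw resident-record table (one row per resident).

    Items are parameterized so the computed indicator prevalences land near
    the configured targets; invalid self-reported-pain answers and missing
    items are injected at ``missingness_rates``.
    """
    records = simulate_covariates(config)
    n = len(records)
    ex = config.exclusion_params
    ex_rng = _rng(config.seed, "exclusions")

    # polypharmacy: ingredient count straddling the >= 9 cut
    y = _latent_outcome(config, records, "polypharmacy")
    rng = _rng(config.seed, "items:polypharmacy")
    rng.random(n)  # skip the latent-outcome draw to decouple the count noise
    count = rng.binomial(8, 0.55, size=n)
    count[y == 1] = 9 + rng.poisson(2.5, size=int((y == 1).sum()))
    records["n_active_ingredients"] = count

    # pain, self-reported and observed
    for ind, prefix in (("pain_self", "pain_self"), ("pain_observed", "pain_obs")):
        y = _latent_outcome(config, records, ind)
        rng = _rng(config.seed, f"items:{ind}")
        rng.random(n)
        freq, inten = _pain_items(y, rng)
        records[f"{prefix}_freq"] = freq
        records[f"{prefix}_intensity"] = inten

    mrng = _rng(config.seed, "missing:pain_self")
    invalid = mrng.random(n) < config.missingness_rates.get("pain_self", 0.0)
    which = mrng.integers(0, 3, size=n)  # freq / intensity / both
    records.loc[invalid & (which != 1), "pain_self_freq"] = "invalid"
    records.loc[invalid & (which != 0), "pain_self_intensity"] = "invalid"

    mrng = _rng(config.seed, "missing:pain_observed")
    miss = mrng.random(n) < config.missingness_rates.get("pain_observed", 0.0)
    records.loc[miss, ["pain_obs_freq", "pain_obs_intensity"]] = pd.NA

    # physical restraints
    for ind, use_col, ctx_col, p_consent in (
        ("restraint_trunk", "trunk_restraint_daily", "trunk_restraint_context", ex.p_trunk_consented),
        ("restraint_bedrails", "bedrails_daily_all_sides", "bedrail_context", ex.p_bedrails_consented),
    ):
        y = _latent_outcome(config, records, ind)
        rng = _rng(config.seed, f"items:{ind}")
        rng.random(n)
        consented = ex_rng.random(n) < p_consent
        use = np.where(consented, True, y == 1)
        context = np.full(n, "none", dtype=object)
        incapable = rng.random(n) < 0.8
        context[use & incapable] = "incapable"
        context[use & ~incapable] = "not_clarified"
        context[consented] = "capable_agreed"
        records[use_col] = use
        records[ctx_col] = context

    mrng = _rng(config.seed, "missing:restraint_bedrails")
    miss = mrng.random(n) < config.missingness_rates.get("restraint_bedrails", 0.0)
    records["bedrails_daily_all_sides"] = records["bedrails_daily_all_sides"].astype(object)
    records.loc[miss, ["bedrails_daily_all_sides", "bedrail_context"]] = pd.NA

    # weight loss and its exclusion items
    y = _latent_outcome(config, records, "weight_loss")
    rng = _rng(config.seed, "items:weight_loss")
    rng.random(n)
    u = rng.random(n)
    loss5 = (y == 1) & (u < 0.65)  # 45% only-30d + 20% both
    loss10 = (y == 1) & (u >= 0.45)
    records["weight_loss_5pct_30d"] = loss5
    records["weight_loss_10pct_180d"] = loss10

    le = np.full(n, "no", dtype=object)
    u = ex_rng.random(n)
    le[u < ex.p_life_expectancy_yes] = "yes"
    le[
        (u >= ex.p_life_expectancy_yes)
        & (u < ex.p_life_expectancy_yes + ex.p_life_expectancy_not_collected)
    ] = "not_collected"
    records["life_expectancy_lt6mo"] = le
    records["is_admission_assessment"] = ex_rng.random(n) < ex.p_admission_assessment

    mrng = _rng(config.seed, "missing:weight_loss")
    miss = mrng.random(n) < config.missingness_rates.get("weight_loss", 0.0)
    records["weight_loss_5pct_30d"] = records["weight_loss_5pct_30d"].astype(object)
    records["weight_loss_10pct_180d"] = records["weight_loss_10pct_180d"].astype(object)
    records.loc[miss, ["weight_loss_5pct_30d", "weight_loss_10pct_180d"]] = pd.NA

    return records.drop(columns=["age"])
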