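"""Construction of the six nursing-home quality indicators.

Each indicator is defined by a numerator predicate, an exclusion predicate
and the raw items it requires.  Residents are classified, per indicator, into
exactly one of three states (the partition invariant):

* ``eligible`` — in the denominator, with a binary ``outcome``;
* ``excluded`` — removed by a stated exclusion criterion
  (consented restraint use, invalid pain self-report, life expectancy under
  six months, assessment-at-admission);
* ``missing_item`` — dropped listwise because a required item is missing.

Indicator results are expressed as a rate per facility; the headline overall
prevalence is the mean of facility rates (with its SD), with the
resident-pooled rate also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INDICATOR_IDS = (
    "polypharmacy",
    "pain_self",
    "pain_observed",
    "restraint_trunk",
    "restraint_bedrails",
    "weight_loss",
)

PAIN_INTENSITY_ORDER = {
    "none": 0,
    "mild": 1,
    "moderate": 2,
    "strong": 3,
    "very_strong_unbearable": 4,
}
_MODERATE = PAIN_INTENSITY_ORDER["moderate"]
_VERY_STRONG = PAIN_INTENSITY_ORDER["very_strong_unbearable"]

SCHEMA_RANGES = {"care_level": (1, 12), "cps": (0, 6), "drs": (0, 14)}


class SchemaError(ValueError):
    """A resident table violates the input schema."""


def validate_records(records: pd.DataFrame) -> None:
    """Validate the resident-table schema, naming the offending row/field."""
    required = ["facility_id", "resident_id", "care_level", "cps", "drs"]
    for col in required:
        if col not in records.columns:
            raise SchemaError(f"missing required column {col!r}")
    for col, (lo, hi) in SCHEMA_RANGES.items():
        vals = pd.to_numeric(records[col], errors="coerce")
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            row = records.index[bad][0]
            raise SchemaError(
                f"column {col!r} out of range [{lo},{hi}] at row {row!r}"
            )


def _pain_outcome(freq: pd.Series, inten: pd.Series) -> pd.Series:
    level = inten.map(PAIN_INTENSITY_ORDER)
    daily_moderate_up = (freq == "daily") & (level >= _MODERATE)
    nondaily_very_strong = (freq == "nondaily") & (level == _VERY_STRONG)
    return (daily_moderate_up | nondaily_very_strong).astype(int)


@dataclass(frozen=True)
class IndicatorDefinition:
    """Numerator / exclusion rules and required items for one indicator."""

    id: str
    required_items: tuple[str, ...]
    description: str
    exclusion_reason: str | None = None

    def exclusions(self, records: pd.DataFrame) -> pd.Series:
        """Boolean mask of residents removed by the stated exclusion rule,
        evaluated before the numerator (among rows with complete items)."""
        idx = records.index
        if self.id == "pain_self":
            return (records["pain_self_freq"] == "invalid") | (
                records["pain_self_intensity"] == "invalid"
            )
        if self.id == "restraint_trunk":
            return records["trunk_restraint_context"] == "capable_agreed"
        if self.id == "restraint_bedrails":
            return records["bedrail_context"] == "capable_agreed"
        if self.id == "weight_loss":
            return (records["life_expectancy_lt6mo"] == "yes") | (
                records["is_admission_assessment"].astype(bool)
            )
        return pd.Series(False, index=idx)

    def outcome(self, records: pd.DataFrame) -> pd.Series:
        if self.id == "polypharmacy":
            return (records["n_active_ingredients"] >= 9).astype(int)
        if self.id == "pain_self":
            return _pain_outcome(
                records["pain_self_freq"], records["pain_self_intensity"]
            )
        if self.id == "pain_observed":
            return _pain_outcome(
                records["pain_obs_freq"], records["pain_obs_intensity"]
            )
        if self.id == "restraint_trunk":
            return records["trunk_restraint_daily"].astype(bool).astype(int)
        if self.id == "restraint_bedrails":
            return records["bedrails_daily_all_sides"].astype(bool).astype(int)
        if self.id == "weight_loss":
            return (
                records["weight_loss_5pct_30d"].astype(bool)
                | records["weight_loss_10pct_180d"].astype(bool)
            ).astype(int)
        raise KeyError(self.id)


INDICATORS: dict[str, IndicatorDefinition] = {
    d.id: d
    for d in (
        IndicatorDefinition(
            "polypharmacy",
            ("n_active_ingredients",),
            "nine or more active ingredients in the last 7 days",
        ),
        IndicatorDefinition(
            "pain_self",
            ("pain_self_freq", "pain_self_intensity"),
            "self-reported daily moderate-or-higher pain, or nondaily "
            "very strong/unbearable pain",
            exclusion_reason="invalid_response",
        ),
        IndicatorDefinition(
            "pain_observed",
            ("pain_obs_freq", "pain_obs_intensity"),
            "observed daily moderate-or-higher pain, or nondaily very "
            "strong/unbearable pain",
        ),
        IndicatorDefinition(
            "restraint_trunk",
            ("trunk_restraint_daily", "trunk_restraint_context"),
            "daily trunk fixation or rise-preventing seating",
            exclusion_reason="consented",
        ),
        IndicatorDefinition(
            "restraint_bedrails",
            ("bedrails_daily_all_sides", "bedrail_context"),
            "daily bedrails or similar devices on all open sides",
            exclusion_reason="consented",
        ),
        IndicatorDefinition(
            "weight_loss",
            (
                "weight_loss_5pct_30d",
                "weight_loss_10pct_180d",
                "life_expectancy_lt6mo",
                "is_admission_assessment",
            ),
            ">=5% weight loss in 30 days or >=10% in 180 days",
            exclusion_reason="terminal_or_admission",
        ),
    )
}


def extract_indicator(records: pd.DataFrame, indicator: str) -> pd.DataFrame:
    """Per-resident eligibility and outcome for one indicator.

    Returns a frame with ``facility_id, resident_id, eligible, outcome,
    exclusion_reason``; ``outcome`` is defined (0/1) exactly when
    ``eligible`` is True.
    """
    if indicator not in INDICATORS:
        raise KeyError(
            f"unknown indicator {indicator!r}; known: {list(INDICATORS)}"
        )
    validate_records(records)
    definition = INDICATORS[indicator]

    out = records[["facility_id", "resident_id"]].copy()
    out["eligible"] = False
    out["outcome"] = pd.array([pd.NA] * len(records), dtype="Int64")
    out["exclusion_reason"] = pd.array([pd.NA] * len(records), dtype="string")

    items = records[list(definition.required_items)]
    missing = items.isna().any(axis=1)
    out.loc[missing, "exclusion_reason"] = "missing_item"

    complete = records.loc[~missing]
    if len(complete):
        excluded = definition.exclusions(complete)
        reason = definition.exclusion_reason or "excluded"
        out.loc[complete.index[excluded], "exclusion_reason"] = reason
        eligible_idx = complete.index[~excluded]
        out.loc[eligible_idx, "eligible"] = True
        out.loc[eligible_idx, "outcome"] = definition.outcome(
            records.loc[eligible_idx]
        ).to_numpy()
    out.attrs["indicator"] = indicator
    return out


def exclusion_audit(extract: pd.DataFrame) -> dict[str, int]:
    """Counts per non-eligibility reason plus eligible/total tallies."""
    reasons = extract.loc[~extract["eligible"], "exclusion_reason"]
    audit = {str(k): int(v) for k, v in reasons.value_counts().items()}
    audit["eligible"] = int(extract["eligible"].sum())
    audit["total"] = int(len(extract))
    return audit


@dataclass
class FacilityRates:
    """Per-facility event rates for one indicator plus overall summaries."""

    indicator: str
    table: pd.DataFrame  # facility_id, n_eligible, n_events, rate
    mean_rate: float  # mean of facility rates (headline prevalence)
    sd_rate: float  # SD of facility rates
    pooled_rate: float  # resident-pooled prevalence
    empty_facilities: list = field(default_factory=list)


def facility_rates(extract: pd.DataFrame) -> FacilityRates:
    """Facility-level rates and the cross-facility mean/SD of rates."""
    if extract.empty:
        raise ValueError("empty extract")
    eligible = extract[extract["eligible"]]
    if eligible.empty:
        raise ValueError("no eligible residents in any facility")
    grp = extract.groupby("facility_id", sort=True)
    tab = pd.DataFrame(
        {
            "n_eligible": grp["eligible"].sum().astype(int),
            "n_events": grp["outcome"].sum().fillna(0).astype(int),
        }
    )
    tab["rate"] = np.where(
        tab["n_eligible"] > 0, tab["n_events"] / tab["n_eligible"].replace(0, 1), np.nan
    )
    empty = tab.index[tab["n_eligible"] == 0].tolist()
    rates = tab.loc[tab["n_eligible"] > 0, "rate"]
    return FacilityRates(
        indicator=extract.attrs.get("indicator", ""),
        table=tab.reset_index(),
        mean_rate=float(rates.mean()),
        sd_rate=float(rates.std(ddof=1)) if len(rates) > 1 else float("nan"),
        pooled_rate=float(eligible["outcome"].mean()),
        empty_facilities=empty,
    )
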