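import pandas as pd
import pytest

from nhqi.simulate import SimulationConfig, simulate_items, simulate_outcomes

#: complete, schema-valid resident row used as the base for boundary fixtures
RECORD_DEFAULTS = {
    "facility_id": "F001",
    "resident_id": "F001-R0001",
    "birth_year": 1931,
    "admission_date": "2015-01-01",
    "assessment_year": 2017,
    "sex": "female",
    "care_level": 5,
    "cps": 2,
    "drs": 1,
    "n_active_ingredients": 4,
    "pain_self_freq": "none",
    "pain_self_intensity": "none",
    "pain_obs_freq": "none",
    "pain_obs_intensity": "none",
    "trunk_restraint_daily": False,
    "trunk_restraint_context": "none",
    "bedrails_daily_all_sides": False,
    "bedrail_context": "none",
    "weight_loss_5pct_30d": False,
    "weight_loss_10pct_180d": False,
    "life_expectancy_lt6mo": "no",
    "is_admission_assessment": False,
}


def make_records(*overrides: dict) -> pd.DataFrame:
    """Build a resident table from per-row override dicts over the defaults."""
    rows = []
    for i, ov in enumerate(overrides or ({},)):
        row = dict(RECORD_DEFAULTS)
        row["resident_id"] = f"F001-R{i + 1:04d}"
        row.update(ov)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_items() -> pd.DataFrame:
    """A 25-facility synthetic bundle shared across read-only tests."""
    cfg = SimulationConfig(n_facilities=25, residents_per_facility=40, seed=42)
    return simulate_items(cfg)


@pytest.fixture(scope="session")
def outcome_frame_5x20() -> pd.DataFrame:
    """Tiny seeded outcome-level frame for likelihood-oracle tests."""
    cfg = SimulationConfig(
        n_facilities=5,
        residents_per_facility=20,
        group_sd=0.8,
        intercept=-1.0,
        fixed_effects={"cps": 0.2},
        seed=11,
    )
    return simulate_outcomes(cfg, ["cps"])
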