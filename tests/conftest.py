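import numpy as np
import pandas as pd
import pytest

from ceapipe.copay import CopayRules
from ceapipe.costing import Tariff
from ceapipe.synth import GeneratorParams, TrialDesign, generate_cohort
from ceapipe.valuation import ValueSet


@pytest.fixture(scope="session")
def toy_vs():
    return ValueSet.toy()


@pytest.fixture
def tariff():
    return Tariff(
        physician_consultation_cost=1000.0,
        specialist_consultation_cost=2000.0,
        avg_cost_per_drg_point=30000.0,
        hcp_hourly_wage_with_social_contributions=500.0,
        daily_wage_by_age_band={b: 1500.0 for b in
                                ("30-39", "40-49", "50-59", "60-69",
                                 "70-79", "80-89", "90-99")},
        social_contribution_rate=0.3142,
    )


@pytest.fixture
def rules():
    return CopayRules()


@pytest.fixture(scope="session")
def small_registers():
    """Deterministic 30-per-arm cohort shared across read-only tests."""
    design = TrialDesign(n_per_arm=30, seed=42)
    return generate_cohort(design, GeneratorParams())


def quiet_params(**overrides):
    """Generator params with no events/deaths/missingness unless overridden."""
    base = dict(
        event_rates={"primary": 0.0, "specialised_outpatient": 0.0,
                     "inpatient": 0.0, "polyclinical": 0.0, "dispensation": 0.0},
        missingness_prob_by_arm_and_visit={
            arm: {m: 0.0 for m in (0, 3, 6, 12, 24)}
            for arm in ("control", "intervention")},
        mortality_hazard=0.0,
        sick_leave_rate=0.0,
        intervention_calls_mean=0.0,
        platform_uses_mean=0.0,
        health_plan_call_prob=0.0,
    )
    base.update(overrides)
    return GeneratorParams(**base)


def make_patients(n=4, arm=("control", "intervention")):
    """Tiny hand-rolled patient register for unit tests."""
    arms = [arm[i % len(arm)] for i in range(n)]
    cyc = lambda lst: [lst[i % len(lst)] for i in range(n)]
    return pd.DataFrame({
        "patient_id": range(n),
        "arm": arms,
        "age": cyc([63.0, 71.0, 55.0, 80.0]),
        "age_band": cyc(["under65", "65plus", "under65", "65plus"]),
        "female": cyc([0, 1]),
        "diagnosis": cyc(["CHF", "COPD", "both", "CHF"]),
        "living_alone": cyc([0, 1]),
        "labour_market": [1] * n,
        "pp_eligible": [0 if a == "control" else 1 for a in arms],
        "death_day": pd.array([pd.NA] * n, dtype="Int64"),
    })
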