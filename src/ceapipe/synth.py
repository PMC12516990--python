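"""Synthetic two-arm trial register generator.

Produces the seven register tables every downstream stage consumes:
patients, EQ-5D responses at scheduled visits, care events with optional
DRG weights, drug dispensations, sick-leave absences, intervention
contact logs and deaths.  All randomness flows from a single seed so a
fixed ``(design, params, seed)`` triple yields a byte-identical bundle.

The generating model is intentionally simple and analytically tractable:

* homogeneous Poisson processes per care stream per patient;
* latent utility = patient random intercept + arm-specific linear slope
  + visit noise, truncated to the 3L scale and discretised to the
  nearest-valued EQ-5D-3L state under the active value set;
* missing-completely-at-random EQ-5D responses per (arm, visit), with an
  optional utility-dependent (MAR) tilt;
* exponential survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .valuation import DIMENSIONS, MIN_UTILITY, ValueSet

ARMS = ("control", "intervention")
AGE_BANDS = ("under65", "65plus")
DIAGNOSES = ("CHF", "COPD", "both")
STREAMS = ("primary", "specialised_outpatient", "inpatient", "polyclinical")
VISIT_FORMS = ("physician", "other_hcp", "group", "team", "group_team",
               "home", "indirect")

RateSpec = Union[float, Mapping[str, float]]


def visit_day(month: int) -> int:
    """Scheduled-visit day for a follow-up month (365-day years)."""
    return int(round(month * 365 / 12))


@dataclass(frozen=True)
class TrialDesign:
    """Stratified 1:1 two-arm design."""

    n_per_arm: int = 110
    strata: Tuple[Tuple[str, str], ...] = tuple(
        (band, dx) for band in AGE_BANDS for dx in DIAGNOSES
    )
    horizon_days: int = 730
    followup_schedule_months: Tuple[int, ...] = (0, 3, 6, 12, 24)
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_per_arm, (int, np.integer)) or isinstance(self.n_per_arm, bool):
            raise TypeError("n_per_arm must be an integer")
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        sched = self.followup_schedule_months
        if len(sched) < 2 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("followup schedule must be strictly increasing, n >= 2")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")


def _default_missingness() -> Dict[str, Dict[int, float]]:
    # the intervention arm roughly doubles the post-baseline missingness
    return {
        "control": {0: 0.02, 3: 0.08, 6: 0.08, 12: 0.10, 24: 0.12},
        "intervention": {0: 0.02, 3: 0.15, 6: 0.16, 12: 0.20, 24: 0.22},
    }


def _default_event_rates() -> Dict[str, RateSpec]:
    # annual per-patient rates; scalars apply to both arms
    return {
        "primary": {"control": 20.0, "intervention": 21.5},
        "specialised_outpatient": {"control": 6.5, "intervention": 5.2},
        "inpatient": {"control": 1.4, "intervention": 1.0},
        "polyclinical": 0.15,
        "dispensation": 24.0,
    }


@dataclass
class GeneratorParams:
    """Knobs of the generating model; defaults mirror the fixture cohort.

    Demographic marginals (age ≈ 70.7, ~46 % women, diagnosis mix
    ≈ 38/52/10) are synthetic placeholders, not a calibration.
    """

    # demographics
    age_mean: float = 70.7
    age_sd: float = 9.4
    women_prob: float = 0.46
    diagnosis_probs: Tuple[float, float, float] = (0.38, 0.52, 0.10)
    living_alone_prob: float = 0.30
    labour_participation_prob_by_age: Dict[str, float] = field(
        default_factory=lambda: {"under65": 0.45, "65plus": 0.02}
    )

    # latent utility trajectory
    baseline_utility_mean: float = 0.78
    baseline_utility_sd: float = 0.14
    control_utility_slope: float = -0.030  # utility units / year
    arm_utility_slope_diff: float = 0.018  # intervention declines slower
    visit_noise_sd: float = 0.05

    # missingness
    missingness_prob_by_arm_and_visit: Dict[str, Dict[int, float]] = field(
        default_factory=_default_missingness
    )
    mar_utility_coef: float = 0.0  # 0 = MCAR; <0 makes low utility likelier missing

    # events
    event_rates: Dict[str, RateSpec] = field(default_factory=_default_event_rates)
    primary_visit_form_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "physician": 0.30, "other_hcp": 0.35, "group": 0.04, "team": 0.05,
            "group_team": 0.02, "home": 0.04, "indirect": 0.20,
        }
    )
    drg_weight_shape: float = 4.0   # gamma; mean = shape * scale
    drg_weight_scale: float = 0.25
    drg_missing_prob: float = 0.23  # specialised outpatient only
    inpatient_nights_mean: float = 3.0
    dispensation_cost_mean: float = 250.0  # SEK ex tax, gamma with shape 2
    dispensation_payable_frac: float = 0.45

    # other registers
    sick_leave_rate: float = 12.0  # days / year, labour-market participants
    mortality_hazard: float = 0.045  # per year
    intervention_call_minutes_mean: float = 35.0
    intervention_calls_mean: float = 4.0
    health_plan_call_prob: float = 0.92
    platform_uses_mean: float = 6.0
    platform_minutes_mean: float = 8.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = [self.women_prob, self.living_alone_prob, self.drg_missing_prob,
                 self.health_plan_call_prob, self.dispensation_payable_frac,
                 *self.labour_participation_prob_by_age.values(),
                 *self.diagnosis_probs, *self.primary_visit_form_probs.values()]
        for arm_probs in self.missingness_prob_by_arm_and_visit.values():
            probs.extend(arm_probs.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.diagnosis_probs) - 1.0) > 1e-9:
            raise ValueError("diagnosis_probs must sum to 1")
        if abs(sum(self.primary_visit_form_probs.values()) - 1.0) > 1e-9:
            raise ValueError("primary_visit_form_probs must sum to 1")
        rates = [self.sick_leave_rate, self.mortality_hazard,
                 self.inpatient_nights_mean, self.platform_uses_mean,
                 self.intervention_calls_mean]
        for spec in self.event_rates.values():
            rates.extend(spec.values() if isinstance(spec, Mapping) else [spec])
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        for arm, arm_probs in self.missingness_prob_by_arm_and_visit.items():
            if 0 in arm_probs:
                later = [p for v, p in arm_probs.items() if v > 0]
                if later and arm_probs[0] > min(later):
                    raise ValueError(
                        f"{arm}: baseline missingness must not exceed later visits"
                    )

    def arm_rate(self, stream: str, arm: str) -> float:
        spec = self.event_rates.get(stream, 0.0)
        if isinstance(spec, Mapping):
            if arm not in spec:
                raise KeyError(f"no {stream!r} rate for arm {arm!r}")
            return float(spec[arm])
        return float(spec)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        d = dict(d)
        miss = d.get("missingness_prob_by_arm_and_visit")
        if miss is not None:
            d["missingness_prob_by_arm_and_visit"] = {
                arm: {int(v): float(p) for v, p in vp.items()}
                for arm, vp in miss.items()
            }
        if "diagnosis_probs" in d:
            d["diagnosis_probs"] = tuple(d["diagnosis_probs"])
        return cls(**d)


# ---------------------------------------------------------------------------


def _allocate_stratified(strata_keys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """1:1 allocation within strata; per-stratum arm counts differ by <= 1.

    Odd-sized strata donate their extra patient to alternating arms so the
    overall arm totals match exactly.
    """
    arms = np.empty(len(strata_keys), dtype=object)
    extra_to = 0  # alternates which arm receives the odd patient
    for key in sorted(set(strata_keys)):
        idx = np.flatnonzero(strata_keys == key)
        idx = rng.permutation(idx)
        half, odd = divmod(len(idx), 2)
        n0 = half + (odd and extra_to == 0)
        if odd:
            extra_to = 1 - extra_to
        arms[idx[:n0]] = ARMS[0]
        arms[idx[n0:]] = ARMS[1]
    return arms


def generate_cohort(
    design: TrialDesign,
    params: Optional[GeneratorParams] = None,
    value_set: Optional[ValueSet] = None,
) -> Dict[str, pd.DataFrame]:
    """Generate the full register bundle for one synthetic trial.

    Returns a dict of DataFrames keyed by register name (see
    :mod:`ceapipe.registers`).  Deterministic for fixed inputs; deaths
    truncate all subsequent events and scheduled utility observations.
    """
    params = params or GeneratorParams()
    params.validate()
    value_set = value_set or ValueSet.toy()
    rng = np.random.default_rng(design.seed)
    n = 2 * design.n_per_arm
    horizon = design.horizon_days

    # --- patients ---------------------------------------------------------
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 30.0, 98.0).round(1)
    band = np.where(age < 65, "under65", "65plus")
    diagnosis = rng.choice(DIAGNOSES, size=n, p=params.diagnosis_probs)
    female = (rng.random(n) < params.women_prob).astype(int)
    living_alone = (rng.random(n) < params.living_alone_prob).astype(int)
    part_prob = np.vectorize(params.labour_participation_prob_by_age.__getitem__)(band)
    labour = (rng.random(n) < part_prob.astype(float)).astype(int)

    strata_keys = np.array([f"{b}|{d}" for b, d in zip(band, diagnosis)])
    arm = _allocate_stratified(strata_keys, rng)

    # --- deaths -----------------------------------------------------------
    if params.mortality_hazard > 0:
        t_death = rng.exponential(1.0 / params.mortality_hazard, n) * 365.0
    else:
        t_death = np.full(n, np.inf)
    death_day = np.where(t_death < horizon, np.floor(t_death), np.nan)
    end_day = np.where(np.isnan(death_day), horizon, death_day)  # exclusive

    patients = pd.DataFrame({
        "patient_id": np.arange(n),
        "arm": arm,
        "age": age,
        "age_band": band,
        "female": female,
        "diagnosis": diagnosis,
        "living_alone": living_alone,
        "labour_market": labour,
        "pp_eligible": 0,
        "death_day": pd.array(death_day, dtype="Int64"),
    })
    deaths = patients.loc[patients["death_day"].notna(), ["patient_id", "death_day"]]
    deaths = deaths.rename(columns={"death_day": "death_day"}).reset_index(drop=True)
    deaths["death_day"] = deaths["death_day"].astype(int)

    # --- EQ-5D trajectories ----------------------------------------------
    slope = np.where(
        arm == "intervention",
        params.control_utility_slope + params.arm_utility_slope_diff,
        params.control_utility_slope,
    )
    intercept = rng.normal(params.baseline_utility_mean, params.baseline_utility_sd, n)
    # questionnaires stop at death; the final visit may fall on the horizon day
    obs_end = np.where(np.isnan(death_day), np.inf, death_day)
    eq_rows = []
    for month in design.followup_schedule_months:
        vd = visit_day(month)
        alive = vd < obs_end
        latent = intercept + slope * (month / 12.0)
        latent = latent + rng.normal(0.0, params.visit_noise_sd, n)
        latent = np.clip(latent, MIN_UTILITY, 1.0)
        codes = value_set.nearest_states(latent)
        for pid in np.flatnonzero(alive):
            eq_rows.append((pid, month, codes[pid]))
    eq5d = pd.DataFrame(eq_rows, columns=["patient_id", "visit_month", "code"])
    for i, dim in enumerate(DIMENSIONS):
        eq5d[dim] = eq5d["code"].str[i].astype("Int64")
    eq5d = eq5d.drop(columns="code").sort_values(
        ["patient_id", "visit_month"]).reset_index(drop=True)

    eq5d = apply_missingness(
        eq5d, patients, params.missingness_prob_by_arm_and_visit,
        seed=rng.integers(2**31), mar_utility_coef=params.mar_utility_coef,
        value_set=value_set,
    )

    # --- care events ------------------------------------------------------
    years_at_risk = end_day / 365.0
    ev_frames = []
    for stream in STREAMS:
        rate = np.array([params.arm_rate(stream, a) for a in arm])
        counts = rng.poisson(rate * years_at_risk)
        pid = np.repeat(np.arange(n), counts)
        days = np.floor(rng.random(counts.sum()) * np.repeat(end_day, counts)).astype(int)
        frame = pd.DataFrame({"patient_id": pid, "day": days})
        frame["stream"] = stream
        if stream == "primary":
            forms = list(params.primary_visit_form_probs)
            probs = list(params.primary_visit_form_probs.values())
            frame["visit_form"] = rng.choice(forms, size=len(frame), p=probs)
            frame["drg_weight"] = np.nan
        else:
            frame["visit_form"] = ""
            w = rng.gamma(params.drg_weight_shape, params.drg_weight_scale, len(frame))
            if stream == "specialised_outpatient" and params.drg_missing_prob > 0:
                w[rng.random(len(frame)) < params.drg_missing_prob] = np.nan
            frame["drg_weight"] = w.round(4)
        frame["nights"] = (
            rng.poisson(params.inpatient_nights_mean, len(frame))
            if stream == "inpatient" else 0
        )
        ev_frames.append(frame)
    care_events = pd.concat(ev_frames, ignore_index=True)
    care_events = care_events.sort_values(
        ["patient_id", "day", "stream"], kind="stable").reset_index(drop=True)

    # --- dispensations ----------------------------------------------------
    disp_rate = np.array([params.arm_rate("dispensation", a) for a in arm])
    counts = rng.poisson(disp_rate * years_at_risk)
    pid = np.repeat(np.arange(n), counts)
    days = np.floor(rng.random(counts.sum()) * np.repeat(end_day, counts)).astype(int)
    cost = rng.gamma(2.0, params.dispensation_cost_mean / 2.0, counts.sum()).round(2)
    dispensations = pd.DataFrame({
        "patient_id": pid, "day": days, "cost_ex_tax": cost,
        "patient_payable": (cost * params.dispensation_payable_frac).round(2),
    }).sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)

    # --- absences ---------------------------------------------------------
    ab_rows = []
    if params.sick_leave_rate > 0:
        workers = np.flatnonzero(labour == 1)
        n_epis = rng.poisson(2.0 * years_at_risk[workers])
        for i, pid_ in enumerate(workers):
            if n_epis[i] == 0:
                continue
            total = rng.poisson(params.sick_leave_rate * years_at_risk[pid_])
            if total == 0:
                continue
            starts = np.sort(np.floor(rng.random(n_epis[i]) * end_day[pid_]).astype(int))
            split = rng.multinomial(total, np.full(n_epis[i], 1.0 / n_epis[i]))
            for day, d in zip(starts, split):
                if d > 0:
                    ab_rows.append((pid_, int(day), int(d)))
    absences = pd.DataFrame(ab_rows, columns=["patient_id", "day", "days"])

    # --- intervention log + PP flag --------------------------------------
    log_rows = []
    pp = np.zeros(n, dtype=int)
    interv = np.flatnonzero(arm == "intervention")
    # intervention delivery happens in the first 6 months
    window = np.minimum(end_day, 182.0)
    for pid_ in interv:
        has_plan_call = rng.random() < params.health_plan_call_prob
        n_calls = int(has_plan_call) + rng.poisson(params.intervention_calls_mean)
        for _ in range(n_calls):
            day = int(rng.random() * window[pid_])
            minutes = round(float(rng.gamma(4.0, params.intervention_call_minutes_mean / 4.0)), 1)
            log_rows.append((pid_, day, "call", minutes))
        n_platform = rng.poisson(params.platform_uses_mean)
        for _ in range(n_platform):
            day = int(rng.random() * window[pid_])
            minutes = round(float(rng.gamma(2.0, params.platform_minutes_mean / 2.0)), 1)
            log_rows.append((pid_, day, "platform", minutes))
        pp[pid_] = int(has_plan_call and n_platform >= 1)
    intervention_log = pd.DataFrame(
        log_rows, columns=["patient_id", "day", "activity", "minutes"]
    ).sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
    patients["pp_eligible"] = pp

    return {
        "patients": patients,
        "eq5d": eq5d,
        "care_events": care_events,
        "dispensations": dispensations,
        "absences": absences,
        "intervention_log": intervention_log,
        "deaths": deaths,
    }


def apply_missingness(
    eq5d: pd.DataFrame,
    patients: pd.DataFrame,
    probs: Mapping[str, Mapping[int, float]],
    seed: int,
    mar_utility_coef: float = 0.0,
    value_set: Optional[ValueSet] = None,
) -> pd.DataFrame:
    """Blank EQ-5D dimensions per (arm, visit) probability; MCAR by default.

    With ``mar_utility_coef`` nonzero the per-row probability is tilted on
    the logit scale by ``coef * (utility − arm/visit mean)``, giving a MAR
    (outcome-dependent) mechanism for imputation testing.

    Raises ``KeyError`` when a visit present in *eq5d* has no probability
    for some arm.  Observed values are never altered.
    """
    rng = np.random.default_rng(seed)
    out = eq5d.copy()
    arm_of = patients.set_index("patient_id")["arm"]
    arms = arm_of.reindex(out["patient_id"]).to_numpy()
    p = np.empty(len(out))
    for i, (a, v) in enumerate(zip(arms, out["visit_month"])):
        try:
            p[i] = probs[a][int(v)]
        except KeyError:
            raise KeyError(f"no missingness probability for arm={a!r}, visit={v}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("missingness probabilities must lie in [0, 1]")
    if mar_utility_coef != 0.0:
        if value_set is None:
            raise ValueError("value_set required for utility-dependent missingness")
        codes = out[list(DIMENSIONS)].astype("Int64").astype(str).agg("".join, axis=1)
        u = np.array([value_set.mapping[c] for c in codes])
        centred = u - np.nanmean(u)
        with np.errstate(divide="ignore"):
            logit = np.log(p / (1 - p))
        logit = logit + mar_utility_coef * centred
        tilted = 1.0 / (1.0 + np.exp(-logit))
        p = np.where((p > 0) & (p < 1), tilted, p)
    drop = rng.random(len(out)) < p
    out.loc[drop, list(DIMENSIONS)] = pd.NA
    for dim in DIMENSIONS:
        out[dim] = out[dim].astype("Int64")
    return out


def expected_utility_gap(params: GeneratorParams, month: int) -> float:
    """Analytic between-arm latent utility gap at *month* (oracle helper)."""
    return params.arm_utility_slope_diff * month / 12.0


def expected_qaly_gap(params: GeneratorParams, discount_rate: float = 0.03) -> float:
    """Analytic QALY gap over 2 years of the linear-gap generating model.

    The latent gap grows linearly g·t, so year-1 area is g/2 and year-2
    area is 3g/2, the latter discounted.
    """
    g = params.arm_utility_slope_diff
    return g * 0.5 + (g * 1.5) / (1.0 + discount_rate)
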