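"""Tariff-based pricing of resource use and per-patient cost bundles.

Prices are carried as exact :class:`fractions.Fraction` amounts (the
one-third telephone multiplier is the only non-terminating one) and
rounded half-up to whole öre only when a component is aggregated, so
repeated runs produce bit-stable tables.

Primary-care visit forms multiply the physician consultation unit cost:
physician ×1, other-HCP and group ×0.4, team and group/team ×1.5, home
×2, indirect (telephone) ×1/3.  DRG-stream events are priced as
weight × average cost per DRG point; a specialised-outpatient event with
a missing weight falls back to the consultation-multiplier method using
the specialist consultation unit cost.  Inpatient and polyclinical
events must carry complete weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

Number = Union[int, float, Fraction]

DEFAULT_MULTIPLIERS: Dict[str, Fraction] = {
    "physician": Fraction(1),
    "other_hcp": Fraction(2, 5),
    "group": Fraction(2, 5),
    "team": Fraction(3, 2),
    "group_team": Fraction(3, 2),
    "home": Fraction(2),
    "indirect": Fraction(1, 3),
}

COST_COMPONENTS = (
    "primary_care",
    "inpatient",
    "specialised_outpatient",
    "polyclinical",
    "prescription_drugs",
    "productivity_loss",
    "intervention_delivery",
)
HEALTHCARE_COMPONENTS = (
    "primary_care", "inpatient", "specialised_outpatient", "polyclinical",
)
STREAM_TO_COMPONENT = {
    "primary": "primary_care",
    "inpatient": "inpatient",
    "specialised_outpatient": "specialised_outpatient",
    "polyclinical": "polyclinical",
}


def _frac(x: Number) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(Decimal(repr(x)))
    return Fraction(x)


def round_sek(x: Number, ndigits: int = 2) -> float:
    """Round a monetary amount half-up to *ndigits* decimals."""
    d = Decimal(x.numerator) / Decimal(x.denominator) if isinstance(x, Fraction) else Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Tariff:
    """Unit prices and wage parameters (2021-style placeholders).

    ``wage_by_age_band`` maps 10-year bands (``"60-69"``) to gross monthly
    wages in SEK; daily wage defaults to monthly × 12 / 365 unless
    ``daily_wage_by_age_band`` overrides it.
    """

    physician_consultation_cost: Number = 1914.0
    specialist_consultation_cost: Number = 3214.0
    avg_cost_per_drg_point: Number = 29239.0
    multipliers: Dict[str, Fraction] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    hcp_hourly_wage_with_social_contributions: Number = 556.0
    wage_by_age_band: Dict[str, Number] = field(default_factory=lambda: {
        "30-39": 36100.0, "40-49": 39500.0, "50-59": 39900.0,
        "60-69": 37800.0, "70-79": 35000.0, "80-89": 35000.0, "90-99": 35000.0,
    })
    daily_wage_by_age_band: Optional[Dict[str, Number]] = None
    social_contribution_rate: float = 0.3142

    def __post_init__(self):
        for name in ("physician_consultation_cost", "specialist_consultation_cost",
                     "avg_cost_per_drg_point",
                     "hcp_hourly_wage_with_social_contributions"):
            if float(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        self.multipliers = {k: _frac(v) for k, v in self.multipliers.items()}

    @classmethod
    def from_yaml(cls, path: str) -> "Tariff":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "multipliers" in raw:
            raw["multipliers"] = {
                k: Fraction(v) if isinstance(v, str) else _frac(v)
                for k, v in raw["multipliers"].items()
            }
        return cls(**raw)

    def daily_wage(self, band: str) -> Fraction:
        if self.daily_wage_by_age_band is not None and band in self.daily_wage_by_age_band:
            return _frac(self.daily_wage_by_age_band[band])
        if band not in self.wage_by_age_band:
            raise KeyError(f"no wage defined for age band {band!r}")
        return _frac(self.wage_by_age_band[band]) * 12 / 365


def age_band_10yr(age: float) -> str:
    """10-year wage band containing *age*, e.g. 63 → ``'60-69'``."""
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


# ---------------------------------------------------------------------------
# event-level pricing
# ---------------------------------------------------------------------------

def price_primary_event(visit_form: str, tariff: Tariff) -> Fraction:
    """Price one primary-care contact by its visit-form multiplier."""
    if visit_form not in tariff.multipliers:
        raise ValueError(f"unknown visit form {visit_form!r}")
    return _frac(tariff.physician_consultation_cost) * tariff.multipliers[visit_form]


def price_drg_event(
    stream: str,
    drg_weight: Optional[float],
    tariff: Tariff,
    visit_form: str = "physician",
) -> Fraction:
    """Price a DRG-stream event: weight × point cost, with the
    specialised-outpatient missing-weight fallback."""
    if stream not in ("inpatient", "polyclinical", "specialised_outpatient"):
        raise ValueError(f"not a DRG-priced stream: {stream!r}")
    missing = drg_weight is None or (isinstance(drg_weight, float) and math.isnan(drg_weight))
    if missing:
        if stream != "specialised_outpatient":
            raise ValueError(
                f"missing DRG weight for {stream} event; inpatient and "
                "polyclinical registers must carry complete weights"
            )
        form = visit_form if visit_form else "physician"
        if form not in tariff.multipliers:
            raise ValueError(f"unknown visit form {form!r}")
        return _frac(tariff.specialist_consultation_cost) * tariff.multipliers[form]
    if drg_weight < 0:
        raise ValueError("DRG weight must be non-negative")
    return _frac(drg_weight) * _frac(tariff.avg_cost_per_drg_point)


def price_care_events(events: pd.DataFrame, tariff: Tariff) -> pd.Series:
    """Exact Fraction price for every care-event row (aligned index)."""
    prices = []
    for row in events.itertuples(index=False):
        if row.stream == "primary":
            prices.append(price_primary_event(row.visit_form, tariff))
        else:
            form = getattr(row, "visit_form", "") or "physician"
            if isinstance(form, float):
                form = "physician"
            prices.append(price_drg_event(row.stream, row.drg_weight, tariff, form))
    return pd.Series(prices, index=events.index, dtype=object)


def price_drugs(dispensations: pd.DataFrame) -> pd.Series:
    """Ex-tax drug cost per dispensation row; rejects negative records."""
    cost = dispensations["cost_ex_tax"]
    if (cost < 0).any():
        bad = dispensations.loc[cost < 0, "patient_id"].tolist()
        raise ValueError(f"negative dispensation cost for patients {bad}")
    return cost.map(_frac)


def price_intervention(
    log: pd.DataFrame,
    tariff: Tariff,
    intervention_ids: Sequence[int],
) -> pd.Series:
    """HCP delivery cost per log row: minutes / 60 × loaded hourly wage.

    Raises on a log entry for a patient outside the intervention arm.
    """
    if (log["minutes"] < 0).any():
        raise ValueError("negative minutes in intervention log")
    outsiders = set(log["patient_id"]) - set(intervention_ids)
    if outsiders:
        raise ValueError(f"intervention log entries for control patients: {sorted(outsiders)}")
    wage = _frac(tariff.hcp_hourly_wage_with_social_contributions)
    return log["minutes"].map(lambda m: _frac(m) / 60 * wage)


def productivity_loss_per_event(
    absences: pd.DataFrame,
    patients: pd.DataFrame,
    tariff: Tariff,
    horizon_days: int = 730,
) -> pd.Series:
    """Value each absence record: days × daily wage(band at randomisation)
    × (1 + social contributions); zero for non-participants in the labour
    market.  The age band is fixed at randomisation."""
    if ((absences["day"] < 0) | (absences["day"] >= horizon_days)).any():
        raise ValueError("absence record outside the study horizon")
    info = patients.set_index("patient_id")
    scr = 1 + _frac(tariff.social_contribution_rate)
    values = []
    for row in absences.itertuples(index=False):
        if info.at[row.patient_id, "labour_market"] != 1:
            values.append(Fraction(0))
            continue
        band = age_band_10yr(float(info.at[row.patient_id, "age"]))
        values.append(_frac(row.days) * tariff.daily_wage(band) * scr)
    return pd.Series(values, index=absences.index, dtype=object)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def _year_of(day: Union[int, np.integer], horizon_days: int) -> int:
    if not (0 <= day < horizon_days):
        raise ValueError(f"event day {day} outside [0, {horizon_days})")
    return 1 if day < 365 else 2


def assemble_bundles(
    patients: pd.DataFrame,
    care_events: pd.DataFrame,
    dispensations: pd.DataFrame,
    absences: pd.DataFrame,
    intervention_log: pd.DataFrame,
    tariff: Tariff,
    discount_rate_costs: float = 0.03,
    copay_totals: Optional[pd.DataFrame] = None,
    horizon_days: int = 730,
) -> pd.DataFrame:
    """Per-patient cost bundle: component × year amounts plus discounted
    perspective totals (SEK, rounded to öre at this final aggregation).

    Year 1 is days 0–364, year 2 days 365–729, assigned by event start
    day.  ``copay_totals`` (patient_id × [year1, year2] out-of-pocket SEK)
    feeds the patient perspective; when absent that column is zero.
    """
    ids = patients["patient_id"].to_numpy()
    interv = patients.loc[patients["arm"] == "intervention", "patient_id"]
    acc: Dict[int, Dict[str, Fraction]] = {
        pid: {f"{c}_y{y}": Fraction(0) for c in COST_COMPONENTS for y in (1, 2)}
        for pid in ids
    }

    def _add(pid, component, day, amount):
        year = _year_of(day, horizon_days)
        acc[pid][f"{component}_y{year}"] += amount

    if len(care_events):
        prices = price_care_events(care_events, tariff)
        for row, price in zip(care_events.itertuples(index=False), prices):
            _add(row.patient_id, STREAM_TO_COMPONENT[row.stream], row.day, price)
    if len(dispensations):
        for row, price in zip(dispensations.itertuples(index=False),
                              price_drugs(dispensations)):
            _add(row.patient_id, "prescription_drugs", row.day, price)
    if len(absences):
        values = productivity_loss_per_event(absences, patients, tariff, horizon_days)
        for row, v in zip(absences.itertuples(index=False), values):
            _add(row.patient_id, "productivity_loss", row.day, v)
    if len(intervention_log):
        costs = price_intervention(intervention_log, tariff, interv)
        for row, c in zip(intervention_log.itertuples(index=False), costs):
            _add(row.patient_id, "intervention_delivery", row.day, c)

    disc = 1 + _frac(discount_rate_costs)
    records = []
    for pid in ids:
        rec = {"patient_id": pid}
        rec.update({k: round_sek(v) for k, v in acc[pid].items()})
        healthcare = {
            y: sum(acc[pid][f"{c}_y{y}"] for c in HEALTHCARE_COMPONENTS)
            for y in (1, 2)
        }
        drugs = {y: acc[pid][f"prescription_drugs_y{y}"] for y in (1, 2)}
        payer = healthcare[1] + drugs[1] + (healthcare[2] + drugs[2]) / disc
        societal = payer
        for comp in ("productivity_loss", "intervention_delivery"):
            societal += acc[pid][f"{comp}_y1"] + acc[pid][f"{comp}_y2"] / disc
        rec["payer_total_disc"] = round_sek(payer)
        rec["societal_total_disc"] = round_sek(societal)
        rec["payer_total_y1"] = round_sek(healthcare[1] + drugs[1])
        rec["societal_total_y1"] = round_sek(
            healthcare[1] + drugs[1] + acc[pid]["productivity_loss_y1"]
            + acc[pid]["intervention_delivery_y1"])
        records.append(rec)
    bundles = pd.DataFrame(records).set_index("patient_id")

    if copay_totals is not None:
        y1 = copay_totals.get("year1", pd.Series(dtype=float)).reindex(bundles.index).fillna(0.0)
        y2 = copay_totals.get("year2", pd.Series(dtype=float)).reindex(bundles.index).fillna(0.0)
        bundles["patient_total_disc"] = (y1 + y2 / float(disc)).round(2)
        bundles["patient_total_y1"] = y1.round(2)
    else:
        bundles["patient_total_disc"] = 0.0
        bundles["patient_total_y1"] = 0.0
    return bundles
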