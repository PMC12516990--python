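"""Patient co-payment simulation under regional fee and ceiling rules.

Three caps operate independently:

* outpatient contacts accumulate toward an annual ceiling (SEK 1150)
  per reimbursement year, assumed to start at randomisation (day 0);
* inpatient nights cost SEK 100 each up to SEK 1500 per 30-consecutive-day
  window, the window anchored at the first charged night not covered by
  an open window;
* benefit-scheme drug co-payments accumulate to an annual SEK 2350 cap.

Each charge is ``min(fee, remaining ceiling balance)``; ledgers keep the
per-event audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import pandas as pd
import yaml

OUTPATIENT_STREAMS = ("primary", "specialised_outpatient", "polyclinical")


@dataclass
class CopayRules:
    """Fee schedule and ceilings; fees are template prices (placeholders).

    ``outpatient_fee_by_type`` is keyed by ``"<stream>"`` with optional
    ``"<stream>:<visit_form>"`` overrides (e.g. a free telephone contact).
    """

    outpatient_fee_by_type: Dict[str, float] = field(default_factory=lambda: {
        "primary": 200.0,
        "primary:indirect": 0.0,
        "specialised_outpatient": 300.0,
        "polyclinical": 300.0,
    })
    outpatient_annual_ceiling: float = 1150.0
    inpatient_fee_per_night: float = 100.0
    inpatient_window_ceiling: float = 1500.0
    inpatient_window_days: int = 30
    home_visit_surcharge: float = 100.0
    drug_annual_ceiling: float = 2350.0
    reimbursement_period_start: int = 0
    period_days: int = 365

    def __post_init__(self):
        if self.inpatient_window_days <= 0 or self.period_days <= 0:
            raise ValueError("window/period lengths must be positive")
        if self.outpatient_annual_ceiling < max(self.outpatient_fee_by_type.values()):
            raise ValueError("annual ceiling must cover a single fee")
        if self.inpatient_window_ceiling < self.inpatient_fee_per_night:
            raise ValueError("window ceiling must cover a single night fee")

    @classmethod
    def from_yaml(cls, path: str) -> "CopayRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def outpatient_fee(self, stream: str, visit_form: str = "") -> float:
        if visit_form:
            key = f"{stream}:{visit_form}"
            if key in self.outpatient_fee_by_type:
                return float(self.outpatient_fee_by_type[key])
        if stream not in self.outpatient_fee_by_type:
            raise KeyError(f"no outpatient fee for stream {stream!r}")
        return float(self.outpatient_fee_by_type[stream])

    def period_of(self, day: int) -> int:
        return (day - self.reimbursement_period_start) // self.period_days


def _check_sorted(df: pd.DataFrame) -> None:
    if not df.groupby("patient_id", sort=False)["day"].apply(
            lambda s: s.is_monotonic_increasing).all():
        raise ValueError("events must be sorted by day within each patient")


def charge_outpatient(events: pd.DataFrame, rules: CopayRules) -> pd.DataFrame:
    """Charge outpatient contacts against the annual ceiling.

    *events* needs ``patient_id, day, stream`` (+ optional ``visit_form``);
    inpatient rows are ignored.  Returns per-event ledger rows with the
    fee, the amount actually charged and the post-charge period balance.
    """
    ev = events[events["stream"].isin(OUTPATIENT_STREAMS)].copy()
    _check_sorted(ev)
    rows = []
    for pid, grp in ev.groupby("patient_id", sort=True):
        balances: Dict[int, float] = {}
        for row in grp.itertuples(index=False):
            form = getattr(row, "visit_form", "") or ""
            if isinstance(form, float):
                form = ""
            fee = rules.outpatient_fee(row.stream, form)
            if row.stream == "primary" and form == "home":
                fee += rules.home_visit_surcharge
            period = rules.period_of(int(row.day))
            used = balances.get(period, 0.0)
            charged = min(fee, max(rules.outpatient_annual_ceiling - used, 0.0))
            balances[period] = used + charged
            rows.append((pid, int(row.day), row.stream, fee, charged,
                         period, balances[period]))
    return pd.DataFrame(rows, columns=[
        "patient_id", "day", "stream", "fee", "charged", "period",
        "period_balance"])


def charge_inpatient(episodes: pd.DataFrame, rules: CopayRules) -> pd.DataFrame:
    """Charge SEK per hospital night under the rolling-window ceiling.

    *episodes* needs ``patient_id, day, nights``; nights occupy days
    ``day .. day+nights-1``.  A window spans ``inpatient_window_days``
    consecutive days from the first charged night outside any open
    window, with charges capped at the window ceiling.
    """
    if (episodes["nights"] < 0).any():
        raise ValueError("negative nights")
    rows = []
    for pid, grp in episodes.groupby("patient_id", sort=True):
        nights_days: List[int] = []
        for row in grp.itertuples(index=False):
            nights_days.extend(range(int(row.day), int(row.day) + int(row.nights)))
        nights_days.sort()
        window_start: Optional[int] = None
        window_used = 0.0
        for day in nights_days:
            if window_start is None or day >= window_start + rules.inpatient_window_days:
                window_start, window_used = day, 0.0
            charged = min(rules.inpatient_fee_per_night,
                          rules.inpatient_window_ceiling - window_used)
            charged = max(charged, 0.0)
            window_used += charged
            rows.append((pid, day, charged, window_start, window_used))
    return pd.DataFrame(rows, columns=[
        "patient_id", "day", "charged", "window_start", "window_balance"])


def charge_drugs(dispensations: pd.DataFrame, rules: CopayRules) -> pd.DataFrame:
    """Accumulate patient-payable drug amounts to the annual cap."""
    if (dispensations["patient_payable"] < 0).any():
        raise ValueError("negative patient-payable amount")
    _check_sorted(dispensations)
    rows = []
    for pid, grp in dispensations.groupby("patient_id", sort=True):
        balances: Dict[int, float] = {}
        for row in grp.itertuples(index=False):
            period = rules.period_of(int(row.day))
            used = balances.get(period, 0.0)
            charged = min(float(row.patient_payable),
                          max(rules.drug_annual_ceiling - used, 0.0))
            balances[period] = used + charged
            rows.append((pid, int(row.day), float(row.patient_payable), charged,
                         period, balances[period]))
    return pd.DataFrame(rows, columns=[
        "patient_id", "day", "payable", "charged", "period", "period_balance"])


def copay_totals_by_patient_year(
    ledgers: Mapping[str, pd.DataFrame],
    patients: pd.DataFrame,
    period_days: int = 365,
) -> pd.DataFrame:
    """Sum charged amounts per patient per study year across all ledgers.

    Returns a frame indexed by patient_id with ``year1``/``year2`` columns,
    zero-filled for patients without charges (all randomised patients keep
    their row — deceased contribute charges, denominators are unchanged).
    """
    totals = pd.DataFrame(
        0.0, index=pd.Index(patients["patient_id"], name="patient_id"),
        columns=["year1", "year2"])
    for ledger in ledgers.values():
        if ledger is None or not len(ledger):
            continue
        year = (ledger["day"] // period_days + 1).clip(upper=2)
        grouped = ledger.assign(year=year).groupby(["patient_id", "year"])["charged"].sum()
        for (pid, y), amount in grouped.items():
            if pid in totals.index:
                totals.loc[pid, f"year{y}"] += amount
    return totals


def patient_perspective_totals(
    ledgers: Mapping[str, pd.DataFrame],
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Per-arm, per-year mean co-payment over all randomised patients."""
    if patients["arm"].nunique() < 1 or not len(patients):
        raise ValueError("empty patient register")
    totals = copay_totals_by_patient_year(ledgers, patients)
    merged = totals.join(patients.set_index("patient_id")["arm"])
    out = merged.groupby("arm")[["year1", "year2"]].mean()
    out.columns = ["mean_copay_year1", "mean_copay_year2"]
    return out
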