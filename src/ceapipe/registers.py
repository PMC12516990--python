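"""Register file schemas and delimited-text I/O.

Every pipeline stage exchanges plain CSV registers keyed by an integer
``patient_id``.  Dates are integer days since randomisation.  Missing
EQ-5D dimensions are empty fields (nullable integers in memory).
"""

from __future__ import annotations

import os
from typing import Dict, Mapping

import pandas as pd

#: register name -> ordered column list
SCHEMAS: Dict[str, list] = {
    "patients": [
        "patient_id", "arm", "age", "age_band", "female", "diagnosis",
        "living_alone", "labour_market", "pp_eligible", "death_day",
    ],
    "eq5d": [
        "patient_id", "visit_month", "mobility", "self_care",
        "usual_activities", "pain_discomfort", "anxiety_depression",
    ],
    "care_events": [
        "patient_id", "day", "stream", "visit_form", "drg_weight", "nights",
    ],
    "dispensations": ["patient_id", "day", "cost_ex_tax", "patient_payable"],
    "absences": ["patient_id", "day", "days"],
    "intervention_log": ["patient_id", "day", "activity", "minutes"],
    "deaths": ["patient_id", "death_day"],
}

_NULLABLE_INT = {
    "eq5d": ["mobility", "self_care", "usual_activities", "pain_discomfort",
             "anxiety_depression"],
    "patients": ["death_day"],
}


def validate_register(name: str, df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *df* does not carry the columns of *name*."""
    if name not in SCHEMAS:
        raise ValueError(f"unknown register {name!r}")
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise ValueError(f"register {name!r} lacks columns {missing}")


def write_registers(registers: Mapping[str, pd.DataFrame], outdir: str) -> Dict[str, str]:
    """Write each register to ``<outdir>/<name>.csv``; returns written paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in registers.items():
        validate_register(name, df)
        path = os.path.join(outdir, f"{name}.csv")
        df[SCHEMAS[name]].to_csv(path, index=False)
        paths[name] = path
    return paths


def read_registers(indir: str) -> Dict[str, pd.DataFrame]:
    """Read every register CSV present in *indir* with canonical dtypes."""
    registers: Dict[str, pd.DataFrame] = {}
    for name, cols in SCHEMAS.items():
        path = os.path.join(indir, f"{name}.csv")
        if not os.path.exists(path):
            continue
        dtype = {c: "Int64" for c in _NULLABLE_INT.get(name, [])}
        df = pd.read_csv(path, dtype=dtype)
        validate_register(name, df)
        registers[name] = df
    if "patients" not in registers:
        raise FileNotFoundError(f"no patients.csv register found in {indir}")
    return registers
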