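"""End-to-end pipeline driver and paper-shaped output tables.

``run_all`` takes one config (registers or a synthesis request, tariff,
co-payment rules, value sets, harness specs) and writes a deterministic
artifact set: demographics table, per-component cost table, harness
results table, CE-plane replicate cloud, group-level utility means, a
JSON summary and a log with stage row counts.  Report rounding: utilities
to 4 decimals, SEK to whole crowns.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import cea, copay as copay_mod, costing, registers as reg, synth, valuation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    registers_dir: Optional[str] = None       # load registers, or...
    synth_n_per_arm: Optional[int] = None     # ...generate them
    synth_params: Optional[dict] = None
    tariff_file: Optional[str] = None
    copay_rules_file: Optional[str] = None
    value_set_files: Dict[str, str] = field(default_factory=dict)
    m_imputations: int = 20
    bootstrap_b: int = 1000
    log_level: str = "INFO"

    def __post_init__(self):
        if self.registers_dir is None and self.synth_n_per_arm is None:
            raise ValueError("config needs registers_dir or synth_n_per_arm")
        for name, path in [("tariff_file", self.tariff_file),
                           ("copay_rules_file", self.copay_rules_file),
                           ("registers_dir", self.registers_dir),
                           *[(f"value_set_files[{k}]", v)
                             for k, v in self.value_set_files.items()]]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


class StageError(RuntimeError):
    """Raised when a named pipeline stage fails."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# analysis assembly shared by run_all and the harness tests
# ---------------------------------------------------------------------------

def compute_analysis_inputs(
    registers: Mapping[str, pd.DataFrame],
    value_sets: Mapping[str, valuation.ValueSet],
    tariff: costing.Tariff,
    copay_rules: Optional[copay_mod.CopayRules],
    specs: Sequence[cea.AnalysisSpec],
    m_imputations: int,
    seed: int,
    schedule: Sequence[int] = (0, 3, 6, 12, 24),
):
    """QALY tables per (value set, effect discount) and cost bundles per
    cost discount, as :func:`ceapipe.cea.run_harness` expects."""
    patients = registers["patients"]
    death_day = patients.set_index("patient_id")["death_day"].astype("Float64").astype(float)

    copay_totals = None
    ledgers = {}
    if copay_rules is not None:
        ev = registers["care_events"].sort_values(["patient_id", "day"], kind="stable")
        ledgers = {
            "outpatient": copay_mod.charge_outpatient(ev, copay_rules),
            "inpatient": copay_mod.charge_inpatient(
                ev[ev["stream"] == "inpatient"], copay_rules),
            "drugs": copay_mod.charge_drugs(
                registers["dispensations"].sort_values(
                    ["patient_id", "day"], kind="stable"), copay_rules),
        }
        copay_totals = copay_mod.copay_totals_by_patient_year(ledgers, patients)

    effect_rates = sorted({s.discount_effects for s in specs})
    cost_rates = sorted({s.discount_costs for s in specs})
    needed_sets = {s.value_set for s in specs}

    qalys_by_vs: Dict[str, Dict[float, pd.DataFrame]] = {}
    for vs_id in needed_sets:
        vs = value_sets[vs_id]
        util = valuation.eq5d_to_utilities(registers["eq5d"], vs)
        wide = valuation.utilities_wide(util, schedule)
        covars = _mi_covariates(patients).reindex(wide.index)
        completed = valuation.impute_missing(
            wide, covars, m=m_imputations, seed=seed, on_all_missing="mean",
            clip=(vs.min_utility, vs.max_utility))
        qalys_by_vs[vs_id] = {
            r: valuation.qaly_table(completed, schedule, r, death_day=death_day)
            for r in effect_rates
        }

    bundles_by_rate = {
        r: costing.assemble_bundles(
            patients, registers["care_events"], registers["dispensations"],
            registers["absences"], registers["intervention_log"], tariff,
            discount_rate_costs=r, copay_totals=copay_totals)
        for r in cost_rates
    }
    return qalys_by_vs, bundles_by_rate, ledgers


def _mi_covariates(patients: pd.DataFrame) -> pd.DataFrame:
    p = patients.set_index("patient_id")
    return pd.DataFrame({
        "intervention": (p["arm"] == "intervention").astype(float),
        "age": p["age"].astype(float),
        "female": p["female"].astype(float),
        "dx_copd": (p["diagnosis"] == "COPD").astype(float),
        "dx_both": (p["diagnosis"] == "both").astype(float),
    })


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

DEMOGRAPHIC_VARIABLES = {
    "age": "continuous",
    "female": "binary",
    "diagnosis": "categorical",
    "living_alone": "binary",
    "labour_market": "binary",
}


def make_table_demographics(patients: pd.DataFrame) -> pd.DataFrame:
    """Per-arm descriptives with between-group p-values (Table-1 analogue)."""
    for col in DEMOGRAPHIC_VARIABLES:
        if col not in patients.columns:
            raise ValueError(f"missing mandatory demographic column {col!r}")
    arms = sorted(patients["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly two arms, got {arms}")
    pvals = cea.compare_groups(patients, DEMOGRAPHIC_VARIABLES).set_index("variable")

    rows = []
    for var, kind in DEMOGRAPHIC_VARIABLES.items():
        p = float(pvals.loc[var, "p_value"])
        if kind == "continuous":
            cells = {
                arm: f"{patients.loc[patients.arm == arm, var].mean():.1f} "
                     f"({patients.loc[patients.arm == arm, var].std():.1f})"
                for arm in arms
            }
            rows.append({"characteristic": f"{var}, mean (SD)", **cells, "p_value": p})
        elif kind == "binary":
            cells = {}
            for arm in arms:
                sub = patients.loc[patients.arm == arm, var]
                cells[arm] = f"{int(sub.sum())} ({100 * sub.mean():.1f}%)"
            rows.append({"characteristic": f"{var}, n (%)", **cells, "p_value": p})
        else:
            for level in sorted(patients[var].unique()):
                cells = {}
                for arm in arms:
                    sub = patients.loc[patients.arm == arm, var]
                    n = int((sub == level).sum())
                    cells[arm] = f"{n} ({100 * n / len(sub):.1f}%)"
                rows.append({"characteristic": f"{var}={level}, n (%)",
                             **cells, "p_value": p})
    return pd.DataFrame(rows)


def make_table_costs(
    bundles: pd.DataFrame,
    patients: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-year mean cost per component per arm, with percentile bootstrap
    CIs and Student's t p-values (Table-2 analogue).  SEK, unrounded."""
    arm_of = patients.set_index("patient_id")["arm"]
    rng = np.random.default_rng(seed)
    rows = []
    for comp in costing.COST_COMPONENTS:
        cols = [f"{comp}_y1", f"{comp}_y2"]
        if any(c not in bundles.columns for c in cols):
            raise ValueError(f"component {comp!r} missing from bundles")
        total = bundles[cols].sum(axis=1)
        by_arm = {}
        for arm in ("control", "intervention"):
            vals = total[arm_of.reindex(total.index) == arm].to_numpy()
            mean = vals.mean()
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boot = vals[idx].mean(axis=1)
            lo, hi = np.quantile(boot, [0.025, 0.975])
            by_arm[arm] = (mean, lo, hi, vals)
        _, p = stats.ttest_ind(by_arm["control"][3], by_arm["intervention"][3],
                               equal_var=True)
        rows.append({
            "component": comp,
            "control_mean": by_arm["control"][0],
            "control_ci_low": by_arm["control"][1],
            "control_ci_high": by_arm["control"][2],
            "intervention_mean": by_arm["intervention"][0],
            "intervention_ci_low": by_arm["intervention"][1],
            "intervention_ci_high": by_arm["intervention"][2],
            "p_value": float(p),
        })
    return pd.DataFrame(rows)


def _round_report(df: pd.DataFrame, sek_cols: Sequence[str], util_cols: Sequence[str] = ()) -> pd.DataFrame:
    out = df.copy()
    for c in sek_cols:
        if c in out.columns:
            out[c] = out[c].round(0)
    for c in util_cols:
        if c in out.columns:
            out[c] = out[c].round(4)
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> str:
    """Run the full pipeline; returns the output directory.

    Raises :class:`StageError` naming the failing stage.  Outputs are
    deterministic for a fixed (config, seed).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ceapipe")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run_all_inner(config)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all_inner(config: RunConfig) -> str:
    out = config.out_dir

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(name, exc) from exc
        logger.info("stage %s completed (seed=%s)", name, config.seed)
        return result

    # registers
    if config.registers_dir is not None:
        registers = stage("load_registers", reg.read_registers, config.registers_dir)
    else:
        params = (synth.GeneratorParams.from_dict(config.synth_params)
                  if config.synth_params else synth.GeneratorParams())
        design = synth.TrialDesign(n_per_arm=config.synth_n_per_arm, seed=config.seed)
        registers = stage("synth", synth.generate_cohort, design, params)
        stage("write_registers", reg.write_registers, registers,
              os.path.join(out, "registers"))
    for name, df in registers.items():
        logger.info("register %s: %d rows", name, len(df))

    # configs
    tariff = (costing.Tariff.from_yaml(config.tariff_file)
              if config.tariff_file else costing.Tariff())
    rules = (copay_mod.CopayRules.from_yaml(config.copay_rules_file)
             if config.copay_rules_file else copay_mod.CopayRules())
    value_sets = {"main": valuation.ValueSet.example_experience_based(),
                  "alt": valuation.ValueSet.example_hypothetical()}
    for vs_id, path in config.value_set_files.items():
        value_sets[vs_id] = valuation.ValueSet.from_csv(path)

    specs = cea.default_harness_specs(bootstrap_b=config.bootstrap_b, seed=config.seed)

    qalys_by_vs, bundles_by_rate, ledgers = stage(
        "analysis_inputs", compute_analysis_inputs,
        registers, value_sets, tariff, rules, specs,
        config.m_imputations, config.seed)

    results_table, results = stage(
        "harness", cea.run_harness, registers, specs, qalys_by_vs, bundles_by_rate)

    table1 = stage("table_demographics", make_table_demographics, registers["patients"])
    bundles_main = bundles_by_rate[0.03]
    table2 = stage("table_costs", make_table_costs, bundles_main,
                   registers["patients"], n_boot=config.bootstrap_b, seed=config.seed)

    copay_table = copay_mod.patient_perspective_totals(ledgers, registers["patients"]) \
        if ledgers else pd.DataFrame()

    # write artifacts
    table1.to_csv(os.path.join(out, "table1_demographics.csv"), index=False)
    sek_cols = [c for c in table2.columns if c.endswith(("_mean", "_low", "_high"))]
    _round_report(table2, sek_cols).to_csv(
        os.path.join(out, "table2_costs.csv"), index=False)
    table3 = _round_report(
        results_table,
        ["delta_c", "delta_c_ci_low", "delta_c_ci_high", "icer"],
        ["delta_e", "delta_e_ci_low", "delta_e_ci_high"])
    table3.to_csv(os.path.join(out, "table3_cea.csv"), index=False)
    main_reps = results["main"].replicates
    pd.DataFrame(main_reps, columns=["delta_e", "delta_c"]).to_csv(
        os.path.join(out, "ce_plane_main.csv"), index=False)
    if len(copay_table):
        copay_table.round(0).to_csv(os.path.join(out, "copay_by_arm_year.csv"))
    bundles_main.to_csv(os.path.join(out, "cost_bundles.csv"))

    summary = {
        "seed": config.seed,
        "n_patients": int(len(registers["patients"])),
        "main": {
            "delta_e": round(results["main"].delta_e, 4),
            "delta_c": round(results["main"].delta_c, 0),
            "label": results["main"].label,
        },
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("wrote outputs to %s", out)
    return out
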