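"""Incremental cost-effectiveness analysis with patient-level bootstrap.

Point estimates are arm mean differences (intervention − control) in
discounted QALYs and costs; uncertainty comes from resampling patients
with replacement within arm, preserving arm sizes.  Multiple-imputation
pooling happens before differencing and before the bootstrap (replicates
resample rows of MI-pooled per-patient data).

Dominance labels follow cost-effectiveness-plane convention: more
effective and cheaper → "dominant"; less effective and costlier →
"dominated"; otherwise the ICER ΔC/ΔE is reported (undefined when
ΔE = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POPULATIONS = ("ITT", "PP", "complete_case", "survivors_only",
               "living_alone", "cohabiting")
PERSPECTIVES = ("societal", "payer", "patient")

LABEL_DOMINANT = "dominant"
LABEL_DOMINATED = "dominated"
LABEL_RATIO = "ratio"
LABEL_UNDEFINED = "undefined"


@dataclass(frozen=True)
class AnalysisSpec:
    """One row of the sensitivity/subgroup harness."""

    spec_id: str
    population: str = "ITT"
    value_set: str = "main"
    discount_costs: float = 0.03
    discount_effects: float = 0.03
    horizon_years: int = 2
    perspective: str = "societal"
    bootstrap_b: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if self.discount_costs < 0 or self.discount_effects < 0:
            raise ValueError("discount rates must be >= 0")
        if self.horizon_years not in (1, 2):
            raise ValueError("horizon_years must be 1 or 2")
        if self.bootstrap_b < 1:
            raise ValueError("bootstrap_b must be >= 1")


@dataclass
class IncrementalResult:
    delta_e: float
    delta_c: float
    label: str
    icer: float  # NaN unless label == 'ratio'
    ci_e: Tuple[float, float] = (np.nan, np.nan)
    ci_c: Tuple[float, float] = (np.nan, np.nan)
    replicates: Optional[np.ndarray] = None  # (B, 2) columns (ΔE, ΔC)


def classify(delta_e: float, delta_c: float) -> Tuple[str, float]:
    """Dominance label and ICER for one (ΔE, ΔC) point.

    Covers all nine sign combinations; ΔE = 0 yields the undefined-ratio
    sentinel (label ``'undefined'``, ICER NaN).
    """
    if delta_e > 0 and delta_c < 0:
        return LABEL_DOMINANT, float("nan")
    if delta_e < 0 and delta_c > 0:
        return LABEL_DOMINATED, float("nan")
    if delta_e == 0:
        return LABEL_UNDEFINED, float("nan")
    return LABEL_RATIO, delta_c / delta_e


def incremental(data: pd.DataFrame) -> IncrementalResult:
    """Point estimates from per-patient ``arm, qaly, cost`` rows."""
    for arm in ("intervention", "control"):
        if (data["arm"] == arm).sum() == 0:
            raise ValueError(f"arm {arm!r} empty after population filter")
    means = data.groupby("arm")[["qaly", "cost"]].mean()
    de = float(means.loc["intervention", "qaly"] - means.loc["control", "qaly"])
    dc = float(means.loc["intervention", "cost"] - means.loc["control", "cost"])
    label, icer = classify(de, dc)
    return IncrementalResult(de, dc, label, icer)


def bootstrap_ce(
    data: pd.DataFrame,
    b: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> IncrementalResult:
    """Point estimates plus percentile CIs from a within-arm bootstrap."""
    if b < 1:
        raise ValueError("bootstrap requires B >= 1")
    res = incremental(data)
    rng = np.random.default_rng(seed)
    cols = {}
    for arm in ("intervention", "control"):
        sub = data.loc[data["arm"] == arm, ["qaly", "cost"]].to_numpy()
        idx = rng.integers(0, len(sub), size=(b, len(sub)))
        cols[arm] = sub[idx].mean(axis=1)  # (B, 2)
    reps = cols["intervention"] - cols["control"]
    alpha = (1 - ci_level) / 2
    lo_e, hi_e = np.quantile(reps[:, 0], [alpha, 1 - alpha])
    lo_c, hi_c = np.quantile(reps[:, 1], [alpha, 1 - alpha])
    return replace(res, ci_e=(float(lo_e), float(hi_e)),
                   ci_c=(float(lo_c), float(hi_c)), replicates=reps)


# ---------------------------------------------------------------------------
# baseline comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    data: pd.DataFrame,
    variables: Mapping[str, str],
    arm_col: str = "arm",
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided between-arm p-values, test chosen by declared type.

    ``variables`` maps column name → ``'continuous'`` (Student's t-test),
    ``'categorical'`` (Pearson χ²) or ``'binary'`` (Fisher's exact).
    """
    arms = sorted(data[arm_col].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly two arms, got {arms}")
    a, b = (data[data[arm_col] == g] for g in arms)
    rows = []
    for var, kind in variables.items():
        if kind == "continuous":
            t, p = stats.ttest_ind(a[var].dropna(), b[var].dropna(),
                                   equal_var=not welch)
            test = "welch_t" if welch else "student_t"
        elif kind == "binary":
            table = pd.crosstab(data[arm_col], data[var]).reindex(arms)
            if table.shape[1] == 1:  # constant variable
                p, test = 1.0, "fisher_exact"
            else:
                _, p = stats.fisher_exact(table.to_numpy())
                test = "fisher_exact"
        elif kind == "categorical":
            table = pd.crosstab(data[arm_col], data[var])
            table = table.loc[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                p, test = 1.0, "chi2"
            elif table.shape == (2, 2) and (table.to_numpy() == 0).any():
                logger.warning("zero cell in %s: falling back to Fisher's exact", var)
                _, p = stats.fisher_exact(table.to_numpy())
                test = "fisher_exact_fallback"
            else:
                _, p, _, _ = stats.chi2_contingency(table.to_numpy())
                test = "chi2"
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        rows.append((var, kind, test, float(p)))
    return pd.DataFrame(rows, columns=["variable", "type", "test", "p_value"])


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def select_population(
    patients: pd.DataFrame,
    population: str,
    eq5d: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Apply an analysis-population filter to the patient register."""
    p = patients
    if population == "ITT":
        return p
    if population == "PP":
        keep = (p["arm"] == "control") | (p["pp_eligible"] == 1)
        return p[keep]
    if population == "survivors_only":
        return p[p["death_day"].isna()]
    if population == "living_alone":
        return p[p["living_alone"] == 1]
    if population == "cohabiting":
        return p[p["living_alone"] == 0]
    if population == "complete_case":
        if eq5d is None:
            raise ValueError("complete_case filter needs the eq5d register")
        from .valuation import DIMENSIONS
        has_missing = (
            eq5d.assign(_miss=eq5d[list(DIMENSIONS)].isna().any(axis=1))
            .groupby("patient_id")["_miss"].any()
        )
        incomplete = set(has_missing.index[has_missing])
        return p[~p["patient_id"].isin(incomplete)]
    raise ValueError(f"unknown population {population!r}")


def perspective_cost_column(perspective: str, horizon_years: int) -> str:
    suffix = "total_disc" if horizon_years == 2 else "total_y1"
    return f"{perspective}_{suffix}"


def run_harness(
    registers: Mapping[str, pd.DataFrame],
    specs: Sequence[AnalysisSpec],
    qalys_by_value_set: Mapping[str, Mapping[float, pd.DataFrame]],
    bundles_by_discount: Mapping[float, pd.DataFrame],
    eq5d: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, Dict[str, IncrementalResult]]:
    """Evaluate every :class:`AnalysisSpec` against precomputed inputs.

    ``qalys_by_value_set[vs_id][rate]`` is a per-patient QALY frame (from
    :func:`ceapipe.valuation.qaly_table`); ``bundles_by_discount[rate]``
    a cost-bundle frame.  Returns a tidy results table plus the full
    :class:`IncrementalResult` per spec id.
    """
    ids = [s.spec_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated spec ids")
    patients = registers["patients"]
    eq5d = eq5d if eq5d is not None else registers.get("eq5d")

    rows = []
    results: Dict[str, IncrementalResult] = {}
    for spec in specs:
        pop = select_population(patients, spec.population, eq5d)
        qalys = qalys_by_value_set[spec.value_set][spec.discount_effects]
        bundles = bundles_by_discount[spec.discount_costs]
        qcol = ("qaly_total_discounted" if spec.horizon_years == 2 else "qaly_year1")
        ccol = perspective_cost_column(spec.perspective, spec.horizon_years)
        data = pd.DataFrame({
            "arm": pop.set_index("patient_id")["arm"],
            "qaly": qalys[qcol].reindex(pop["patient_id"]),
            "cost": bundles[ccol].reindex(pop["patient_id"]),
        }).dropna()
        res = bootstrap_ce(data, b=spec.bootstrap_b, seed=spec.seed)
        results[spec.spec_id] = res
        rows.append({
            "spec_id": spec.spec_id,
            "population": spec.population,
            "value_set": spec.value_set,
            "perspective": spec.perspective,
            "horizon_years": spec.horizon_years,
            "discount_costs": spec.discount_costs,
            "discount_effects": spec.discount_effects,
            "n_intervention": int((data["arm"] == "intervention").sum()),
            "n_control": int((data["arm"] == "control").sum()),
            "delta_e": res.delta_e,
            "delta_e_ci_low": res.ci_e[0],
            "delta_e_ci_high": res.ci_e[1],
            "delta_c": res.delta_c,
            "delta_c_ci_low": res.ci_c[0],
            "delta_c_ci_high": res.ci_c[1],
            "icer": res.icer,
            "label": res.label,
        })
    return pd.DataFrame(rows), results


def default_harness_specs(bootstrap_b: int = 1000, seed: int = 0) -> List[AnalysisSpec]:
    """Main analysis plus the standard sensitivity and subgroup battery."""
    base = dict(bootstrap_b=bootstrap_b, seed=seed)
    return [
        AnalysisSpec("main", **base),
        AnalysisSpec("uk_value_set", value_set="alt", **base),
        AnalysisSpec("discount_5pct", discount_costs=0.05, discount_effects=0.05, **base),
        AnalysisSpec("effects_undiscounted", discount_effects=0.0, **base),
        AnalysisSpec("horizon_1yr", horizon_years=1, **base),
        AnalysisSpec("per_protocol", population="PP", **base),
        AnalysisSpec("complete_case", population="complete_case", **base),
        AnalysisSpec("survivors_only", population="survivors_only", **base),
        AnalysisSpec("living_alone", population="living_alone", **base),
        AnalysisSpec("cohabiting", population="cohabiting", **base),
        AnalysisSpec("payer_perspective", perspective="payer", **base),
        AnalysisSpec("patient_perspective", perspective="patient", **base),
    ]
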