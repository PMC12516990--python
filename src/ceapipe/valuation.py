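"""EQ-5D-3L valuation, multiple imputation and discounted QALY accrual.

A health state is a 5-digit code over the dimensions mobility, self-care,
usual activities, pain/discomfort and anxiety/depression, each at level
1 (no problems), 2 (some problems) or 3 (severe problems).  A value set
maps all 243 states to utility weights; published coefficient tables are
deliberately not shipped — sets are loaded from user config, and closed-form
synthetic sets are provided for testing and default pipelines.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: conventional lower bound of the 3L utility scale
MIN_UTILITY = -0.594

ALL_STATE_CODES: Tuple[str, ...] = tuple(
    "".join(map(str, levels)) for levels in itertools.product((1, 2, 3), repeat=5)
)


@dataclass(frozen=True)
class EQ5D3LState:
    """One EQ-5D-3L health state; levels are 1, 2 or 3 per dimension."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise ValueError(f"{dim} level must be 1, 2 or 3, got {level!r}")

    @property
    def code(self) -> str:
        """Canonical 5-digit code, e.g. ``'11223'``."""
        return "".join(str(getattr(self, d)) for d in DIMENSIONS)

    @classmethod
    def from_code(cls, code: str) -> "EQ5D3LState":
        code = str(code)
        if len(code) != 5 or any(c not in "123" for c in code):
            raise ValueError(f"malformed EQ-5D-3L code {code!r}")
        return cls(*(int(c) for c in code))

    @property
    def levels(self) -> Tuple[int, ...]:
        return tuple(getattr(self, d) for d in DIMENSIONS)


@dataclass
class ValueSet:
    """Mapping of all 243 EQ-5D-3L states to utility weights (≤ 1)."""

    name: str
    mapping: Dict[str, float]
    _codes: np.ndarray = field(init=False, repr=False)
    _values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if set(self.mapping) != set(ALL_STATE_CODES):
            raise ValueError(
                f"value set {self.name!r} must map exactly the 243 EQ-5D-3L "
                f"states ({len(self.mapping)} given)"
            )
        vmax = max(self.mapping.values())
        if vmax > 1.0 + 1e-12:
            raise ValueError(f"value set {self.name!r} has weights above 1")
        if self.mapping["11111"] != vmax:
            raise ValueError(
                f"value set {self.name!r}: state 11111 must carry the maximum weight"
            )
        # sorted lookup arrays for nearest-value discretisation
        order = sorted(ALL_STATE_CODES, key=lambda c: (self.mapping[c], c))
        object.__setattr__(self, "_codes", np.array(order))
        object.__setattr__(self, "_values", np.array([self.mapping[c] for c in order]))

    def __getitem__(self, code: str) -> float:
        return self.mapping[code]

    @property
    def max_utility(self) -> float:
        return float(self._values[-1])

    @property
    def min_utility(self) -> float:
        return float(self._values[0])

    def nearest_state(self, utility: float) -> str:
        """Code of the state whose weight is closest to *utility*.

        Ties resolve to the lexicographically smallest code so the mapping
        is deterministic.
        """
        return self.nearest_states(np.asarray([utility]))[0]

    def nearest_states(self, utilities: np.ndarray) -> np.ndarray:
        u = np.asarray(utilities, dtype=float)
        idx = np.searchsorted(self._values, u)
        idx = np.clip(idx, 1, len(self._values) - 1)
        left = self._values[idx - 1]
        right = self._values[idx]
        # half-open tie-break toward the lower-utility side is irrelevant for
        # continuous inputs; <= keeps it deterministic
        pick_left = (u - left) <= (right - u)
        final = np.where(pick_left, idx - 1, idx)
        return self._codes[final]

    # ---- construction helpers -------------------------------------------

    @classmethod
    def toy(cls) -> "ValueSet":
        """Closed-form test set: utility = 1 − 0.1·Σ(level−1)."""
        mapping = {
            code: round(1.0 - 0.1 * sum(int(c) - 1 for c in code), 10)
            for code in ALL_STATE_CODES
        }
        return cls("toy_linear", mapping)

    @classmethod
    def additive(
        cls,
        name: str,
        full_health: float,
        decrements: Mapping[str, Sequence[float]],
        severe_any_extra: float = 0.0,
    ) -> "ValueSet":
        """Additive-decrement set: ``full_health − Σ dec[dim][level−1] − extra``.

        *decrements* maps each dimension to (level-1, level-2, level-3)
        decrements with the level-1 entry 0.  ``severe_any_extra`` is an
        additional decrement applied once if any dimension is at level 3.
        """
        mapping = {}
        for code in ALL_STATE_CODES:
            u = full_health
            for dim, c in zip(DIMENSIONS, code):
                u -= decrements[dim][int(c) - 1]
            if "3" in code:
                u -= severe_any_extra
            mapping[code] = round(u, 10)
        return cls(name, mapping)

    @classmethod
    def example_experience_based(cls) -> "ValueSet":
        """Synthetic stand-in for an experience-based set (mild decrements)."""
        dec = {
            "mobility": (0.0, 0.051, 0.163),
            "self_care": (0.0, 0.042, 0.131),
            "usual_activities": (0.0, 0.045, 0.117),
            "pain_discomfort": (0.0, 0.060, 0.205),
            "anxiety_depression": (0.0, 0.071, 0.237),
        }
        return cls.additive("example_experience", 0.969, dec)

    @classmethod
    def example_hypothetical(cls) -> "ValueSet":
        """Synthetic stand-in for a hypothetical public set (steep, can go < 0)."""
        dec = {
            "mobility": (0.0, 0.069, 0.314),
            "self_care": (0.0, 0.104, 0.214),
            "usual_activities": (0.0, 0.036, 0.094),
            "pain_discomfort": (0.0, 0.123, 0.386),
            "anxiety_depression": (0.0, 0.071, 0.236),
        }
        return cls.additive("example_hypothetical", 1.0, dec, severe_any_extra=0.269)

    # ---- delimited-text round trip --------------------------------------

    @classmethod
    def from_csv(cls, path: str) -> "ValueSet":
        """Read a 243-row ``state_code,utility`` table.

        Lines starting with ``#`` form the metadata header; a ``# name:``
        line supplies the set's identifier.
        """
        name = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    meta = line.lstrip("#").strip()
                    if meta.lower().startswith("name:"):
                        name = meta.split(":", 1)[1].strip()
                    continue
                if line.lower().startswith("state_code"):
                    continue
                code, value = line.split(",")[:2]
                rows.append((code.strip(), float(value)))
        if name is None:
            raise ValueError(f"value set file {path} lacks a '# name:' header")
        return cls(name, dict(rows))

    def to_csv(self, path: str, source: str = "synthetic") -> None:
        with open(path, "w") as fh:
            fh.write(f"# name: {self.name}\n")
            fh.write(f"# source: {source}\n")
            fh.write(f"# range: [{self.min_utility}, {self.max_utility}]\n")
            fh.write("state_code,utility\n")
            for code in ALL_STATE_CODES:
                fh.write(f"{code},{self.mapping[code]}\n")


def value_state(state, value_set: ValueSet) -> float:
    """Utility weight of *state* (an :class:`EQ5D3LState` or a 5-digit code)."""
    code = state.code if isinstance(state, EQ5D3LState) else EQ5D3LState.from_code(state).code
    try:
        return value_set.mapping[code]
    except KeyError:  # pragma: no cover - ValueSet validation forbids this
        raise KeyError(f"state {code} absent from value set {value_set.name!r}")


def eq5d_to_utilities(eq5d: pd.DataFrame, value_set: ValueSet) -> pd.DataFrame:
    """Value an eq5d register to ``patient_id, visit_month, utility``.

    Rows with any missing dimension yield NaN utility.
    """
    out = eq5d[["patient_id", "visit_month"]].copy()
    dims = eq5d[list(DIMENSIONS)]
    complete = dims.notna().all(axis=1)
    codes = dims.astype("Int64").astype(str).agg("".join, axis=1)
    utility = np.full(len(eq5d), np.nan)
    utility[complete.to_numpy()] = [
        value_set.mapping[c] for c in codes[complete]
    ]
    out["utility"] = utility
    return out


def utilities_wide(utilities: pd.DataFrame, schedule: Sequence[int]) -> pd.DataFrame:
    """Pivot long utilities to one row per patient, one column per month."""
    wide = utilities.pivot(index="patient_id", columns="visit_month", values="utility")
    return wide.reindex(columns=list(schedule))


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def impute_missing(
    wide: pd.DataFrame,
    covariates: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 10,
    on_all_missing: str = "raise",
    clip: Tuple[float, float] = (MIN_UTILITY, 1.0),
) -> List[pd.DataFrame]:
    """Chained-equations Bayesian-normal imputation on the utility scale.

    Parameters
    ----------
    wide
        Patients × visit-months utility table (NaN = missing).
    covariates
        Complete numeric predictor table aligned on ``wide.index``
        (arm indicator, age, sex, diagnosis dummies, ...).
    m
        Number of completed tables; they differ only at originally
        missing cells.
    on_all_missing
        ``'raise'`` (default), ``'exclude'`` or ``'mean'`` — policy for
        patients with no observed utility at any visit.

    Returns ``m`` completed copies; downstream pooling follows Rubin's
    rules (:func:`rubin_pool`).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not wide.index.equals(covariates.index):
        covariates = covariates.reindex(wide.index)
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete")

    all_missing = wide.isna().all(axis=1)
    if all_missing.any():
        ids = list(wide.index[all_missing])
        if on_all_missing == "raise":
            raise ValueError(
                f"patients with zero observed utilities: {ids}; "
                "set on_all_missing='exclude' or 'mean'"
            )
        elif on_all_missing == "exclude":
            logger.warning("excluding %d patients with no observed utility: %s",
                           len(ids), ids)
            wide = wide.loc[~all_missing]
            covariates = covariates.loc[~all_missing]
        elif on_all_missing == "mean":
            logger.warning("mean-imputing %d patients with no observed utility: %s",
                           len(ids), ids)
        else:
            raise ValueError(f"unknown on_all_missing policy {on_all_missing!r}")

    cols = list(wide.columns)
    Y0 = wide.to_numpy(dtype=float)
    miss = np.isnan(Y0)
    X = np.column_stack([np.ones(len(wide)), covariates.to_numpy(dtype=float)])

    if not miss.any():
        return [wide.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    col_means = np.nanmean(Y0, axis=0)
    completed = []
    for _ in range(m):
        Y = Y0.copy()
        for j in range(Y.shape[1]):
            Y[miss[:, j], j] = col_means[j]
        for _ in range(n_iter):
            for j in range(Y.shape[1]):
                mj = miss[:, j]
                if not mj.any():
                    continue
                others = [k for k in range(Y.shape[1]) if k != j]
                D = np.column_stack([X, Y[:, others]])
                yobs, Dobs = Y[~mj, j], D[~mj]
                beta, sigma = _bayes_lm_draw(Dobs, yobs, rng)
                Y[mj, j] = D[mj] @ beta + rng.normal(0.0, sigma, mj.sum())
        np.clip(Y, clip[0], clip[1], out=Y)
        Y[~miss] = Y0[~miss]  # observed cells are inviolate
        completed.append(pd.DataFrame(Y, index=wide.index, columns=cols))
    return completed


def _bayes_lm_draw(D: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Draw (beta, sigma) from the approximate posterior of an OLS fit."""
    n, p = D.shape
    # ridge jitter keeps the draw defined under collinearity / tiny n
    DtD = D.T @ D + 1e-8 * np.eye(p)
    DtDinv = np.linalg.inv(DtD)
    beta_hat = DtDinv @ (D.T @ y)
    resid = y - D @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    L = np.linalg.cholesky(DtDinv * sigma2 + 1e-12 * np.eye(p))
    beta = beta_hat + L @ rng.standard_normal(p)
    return beta, np.sqrt(sigma2)


def rubin_pool(estimates: Sequence[float], variances: Sequence[float]):
    """Pool *m* completed-data estimates by Rubin's rules.

    Returns ``(pooled_estimate, total_variance)`` where the total variance
    is within + (1 + 1/m) · between.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    qbar = q.mean()
    within = u.mean()
    between = q.var(ddof=1) if m > 1 else 0.0
    return float(qbar), float(within + (1 + 1 / m) * between)


# ---------------------------------------------------------------------------
# QALY accrual
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QALYResult:
    patient_id: int
    qaly_year1: float
    qaly_year2_undiscounted: float
    qaly_total_discounted: float
    discount_rate_effects: float


def qaly_auc(
    times_months: Sequence[float],
    utilities: Sequence[float],
    discount_rate_effects: float = 0.03,
    death_time_months: Optional[float] = None,
    patient_id: int = -1,
) -> QALYResult:
    """Trapezoidal area under the utility curve, split at the year boundary.

    Year-1 area covers months 0–12, year-2 months 12–24; the second-year
    area enters the discounted total divided by ``1 + rate``.  A death at
    time *d* contributes a linear segment from the last observation before
    *d* down to utility 0 at *d* and zero utility thereafter.
    """
    t = np.asarray(times_months, dtype=float)
    u = np.asarray(utilities, dtype=float)
    if t.shape != u.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("times and utilities must be equal-length 1-D, n >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("visit times must be strictly increasing")
    horizon = float(t[-1])

    if death_time_months is not None and death_time_months < horizon:
        d = float(death_time_months)
        keep = t < d
        if not keep.any():
            pts_t = np.array([0.0, horizon])
            pts_u = np.array([0.0, 0.0])
        else:
            if np.isnan(u[keep]).any():
                raise ValueError("utilities must be complete (post-imputation)")
            pts_t = np.concatenate([t[keep], [d, horizon]])
            pts_u = np.concatenate([u[keep], [0.0, 0.0]])
    else:
        if np.isnan(u).any():
            raise ValueError("utilities must be complete (post-imputation)")
        pts_t, pts_u = t, u

    year1 = _piecewise_area(pts_t, pts_u, 0.0, min(12.0, horizon)) / 12.0
    year2 = _piecewise_area(pts_t, pts_u, 12.0, horizon) / 12.0 if horizon > 12 else 0.0
    total = year1 + year2 / (1.0 + discount_rate_effects)
    return QALYResult(patient_id, float(year1), float(year2), float(total),
                      discount_rate_effects)


def _piecewise_area(t: np.ndarray, u: np.ndarray, a: float, b: float) -> float:
    """Integral of the piecewise-linear curve (t, u) over [a, b]."""
    if b <= a:
        return 0.0
    grid = np.union1d(t, [a, b])
    grid = grid[(grid >= a) & (grid <= b)]
    vals = np.interp(grid, t, u)
    return float(np.trapezoid(vals, grid))


def qaly_table(
    completed: Sequence[pd.DataFrame],
    schedule: Sequence[int],
    discount_rate_effects: float,
    death_day: Optional[pd.Series] = None,
    horizon_months: int = 24,
) -> pd.DataFrame:
    """Per-patient QALYs pooled over MI tables.

    Returns a frame indexed by patient with ``qaly_year1``,
    ``qaly_year2_undiscounted`` and ``qaly_total_discounted`` columns,
    each the mean over the *m* completed tables.
    """
    sched = [s for s in schedule if s <= horizon_months]
    acc = None
    for tbl in completed:
        rows = []
        for pid, row in tbl[sched].iterrows():
            death_m = None
            if death_day is not None and pid in death_day.index and pd.notna(death_day.loc[pid]):
                death_m = float(death_day.loc[pid]) * 12.0 / 365.0
            res = qaly_auc(sched, row.to_numpy(), discount_rate_effects,
                           death_time_months=death_m, patient_id=pid)
            rows.append((pid, res.qaly_year1, res.qaly_year2_undiscounted,
                         res.qaly_total_discounted))
        frame = pd.DataFrame(
            rows, columns=["patient_id", "qaly_year1", "qaly_year2_undiscounted",
                           "qaly_total_discounted"]
        ).set_index("patient_id")
        acc = frame if acc is None else acc + frame
    return acc / len(completed)


def group_mean_utility(
    completed: Sequence[pd.DataFrame],
    patients: pd.DataFrame,
    arm: str,
    visit_month: int,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """Pooled mean utility of *arm* at *visit_month* with a percentile CI.

    Pools over imputations first (per-patient average across completed
    tables), then bootstraps patients.
    """
    ids = patients.loc[patients["arm"] == arm, "patient_id"]
    if len(ids) == 0:
        raise ValueError(f"empty arm {arm!r}")
    pooled = sum(tbl[visit_month] for tbl in completed) / len(completed)
    values = pooled.reindex(ids).dropna().to_numpy()
    if len(values) == 0:
        raise ValueError(f"no utilities for arm {arm!r} at month {visit_month}")
    mean = float(values.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot = values[idx].mean(axis=1)
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    return mean, (float(lo), float(hi))
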