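import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ceapipe.cea import (
    AnalysisSpec, IncrementalResult, bootstrap_ce, classify, compare_groups,
    default_harness_specs, incremental, run_harness, select_population,
)


class TestClassify:
    # all nine sign combinations of (dE, dC)
    @pytest.mark.parametrize("de,dc,label", [
        (1.0, -1.0, "dominant"),
        (1.0, 1.0, "ratio"),
        (1.0, 0.0, "ratio"),
        (-1.0, 1.0, "dominated"),
        (-1.0, -1.0, "ratio"),
        (-1.0, 0.0, "ratio"),
        (0.0, 1.0, "undefined"),
        (0.0, -1.0, "undefined"),
        (0.0, 0.0, "undefined"),
    ])
    def test_quadrant_logic(self, de, dc, label):
        got, icer = classify(de, dc)
        assert got == label
        if label == "ratio":
            assert icer == pytest.approx(dc / de)
        else:
            assert np.isnan(icer)

    def test_headline_point_is_dominant(self):
        # more effective (+0.0469 QALYs) and cheaper (-68 533.12 SEK)
        label, icer = classify(0.0469, -68533.12)
        assert label == "dominant"
        assert np.isnan(icer)

    def test_ratio_arithmetic(self):
        label, icer = classify(0.05, 100000.0)
        assert label == "ratio"
        assert icer == pytest.approx(2_000_000.0)


def _ce_data(n_per_arm=50, de=0.0, dc=0.0, seed=0, sd_q=0.2, sd_c=1000.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    arm = np.array(["control", "intervention"] * n_per_arm)
    shift = arm == "intervention"
    return pd.DataFrame({
        "arm": arm,
        "qaly": rng.normal(1.5, sd_q, n) + de * shift,
        "cost": rng.normal(50000, sd_c, n) + dc * shift,
    })


class TestIncremental:
    def test_mean_differences(self):
        data = pd.DataFrame({
            "arm": ["control", "control", "intervention", "intervention"],
            "qaly": [1.0, 1.2, 1.3, 1.5],
            "cost": [100.0, 200.0, 50.0, 150.0],
        })
        res = incremental(data)
        assert res.delta_e == pytest.approx(0.3)
        assert res.delta_c == pytest.approx(-50.0)
        assert res.label == "dominant"

    def test_empty_arm_rejected(self):
        data = _ce_data(5)
        with pytest.raises(ValueError, match="empty"):
            incremental(data[data["arm"] == "control"])


class TestBootstrap:
    def test_degenerate_cohort_zero_width_ci(self):
        data = pd.DataFrame({
            "arm": ["control"] * 5 + ["intervention"] * 5,
            "qaly": [1.0] * 5 + [1.2] * 5,
            "cost": [10.0] * 5 + [20.0] * 5,
        })
        res = bootstrap_ce(data, b=200, seed=1)
        assert res.ci_e == (pytest.approx(0.2), pytest.approx(0.2))
        assert res.ci_c == (pytest.approx(10.0), pytest.approx(10.0))

    def test_seed_determinism(self):
        data = _ce_data(40, seed=2)
        a = bootstrap_ce(data, b=300, seed=9)
        b = bootstrap_ce(data, b=300, seed=9)
        assert np.array_equal(a.replicates, b.replicates)
        assert bootstrap_ce(data, b=300, seed=10).ci_e != a.ci_e

    def test_replicates_preserve_arm_sizes_shape(self):
        data = _ce_data(30, seed=3)
        res = bootstrap_ce(data, b=123, seed=0)
        assert res.replicates.shape == (123, 2)

    def test_bootstrap_mean_converges_to_point_estimate(self):
        data = _ce_data(100, de=0.05, dc=-2000.0, seed=4)
        res = bootstrap_ce(data, b=5000, seed=5)
        se_e = res.replicates[:, 0].std(ddof=1)
        se_c = res.replicates[:, 1].std(ddof=1)
        assert abs(res.replicates[:, 0].mean() - res.delta_e) < 3 * se_e / np.sqrt(5000)
        assert abs(res.replicates[:, 1].mean() - res.delta_c) < 3 * se_c / np.sqrt(5000)

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ce(_ce_data(5), b=0)


class TestCompareGroups:
    def test_identical_arms_t_test_p_one(self):
        data = pd.DataFrame({
            "arm": ["control"] * 4 + ["intervention"] * 4,
            "x": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        out = compare_groups(data, {"x": "continuous"})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_balanced_2x2_fisher_p_one(self):
        data = pd.DataFrame({
            "arm": ["control"] * 20 + ["intervention"] * 20,
            "flag": ([0] * 10 + [1] * 10) * 2,
        })
        out = compare_groups(data, {"flag": "binary"})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # oracle: enumerate all tables with fixed margins, sum P <= P(obs)
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 12, 4)
            table = np.array([[a, b], [c, d]])
            _, p_scipy = stats.fisher_exact(table)
            n1, n2 = a + b, c + d
            k = a + c
            pmf = [stats.hypergeom.pmf(x, n1 + n2, n1, k)
                   for x in range(max(0, k - n2), min(k, n1) + 1)]
            p_obs = stats.hypergeom.pmf(a, n1 + n2, n1, k)
            p_enum = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
            assert p_scipy == pytest.approx(p_enum, rel=1e-6)
            data = pd.DataFrame({
                "arm": ["control"] * n1 + ["intervention"] * n2,
                "v": [1] * a + [0] * b + [1] * c + [0] * d,
            })
            out = compare_groups(data, {"v": "binary"})
            assert out.loc[0, "p_value"] == pytest.approx(p_enum, rel=1e-6)

    def test_categorical_uses_chi2(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({
            "arm": rng.choice(["control", "intervention"], 200),
            "cat": rng.choice(["a", "b", "c"], 200),
        })
        out = compare_groups(data, {"cat": "categorical"})
        table = pd.crosstab(data["arm"], data["cat"])
        _, p, _, _ = stats.chi2_contingency(table)
        assert out.loc[0, "test"] == "chi2"
        assert out.loc[0, "p_value"] == pytest.approx(p)

    def test_zero_margin_falls_back_to_fisher(self, caplog):
        data = pd.DataFrame({
            "arm": ["control"] * 10 + ["intervention"] * 10,
            "cat": ["x"] * 10 + ["x"] * 5 + ["y"] * 5,
        })
        out = compare_groups(data, {"cat": "categorical"})
        assert out.loc[0, "test"] == "fisher_exact_fallback"

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(_ce_data(5), {"qaly": "weird"})


class TestAnalysisSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            AnalysisSpec("x", population="nope")
        with pytest.raises(ValueError):
            AnalysisSpec("x", discount_costs=-0.01)
        with pytest.raises(ValueError):
            AnalysisSpec("x", horizon_years=3)
        with pytest.raises(ValueError):
            AnalysisSpec("x", bootstrap_b=0)


class TestSelectPopulation:
    def _patients(self):
        return pd.DataFrame({
            "patient_id": range(6),
            "arm": ["control", "intervention"] * 3,
            "pp_eligible": [0, 1, 0, 0, 0, 1],
            "death_day": pd.array([pd.NA, pd.NA, 100, pd.NA, pd.NA, pd.NA],
                                  dtype="Int64"),
            "living_alone": [1, 0, 1, 0, 1, 0],
        })

    def test_pp_subset_of_itt_intervention(self):
        p = self._patients()
        pp = select_population(p, "PP")
        itt_interv = set(p.loc[p["arm"] == "intervention", "patient_id"])
        pp_interv = set(pp.loc[pp["arm"] == "intervention", "patient_id"])
        assert pp_interv <= itt_interv
        assert set(pp.loc[pp["arm"] == "control", "patient_id"]) == \
            set(p.loc[p["arm"] == "control", "patient_id"])

    def test_survivors_only_drops_deceased(self):
        out = select_population(self._patients(), "survivors_only")
        assert 2 not in set(out["patient_id"])

    def test_living_alone_and_cohabiting_partition(self):
        p = self._patients()
        alone = select_population(p, "living_alone")
        co = select_population(p, "cohabiting")
        assert set(alone["patient_id"]) | set(co["patient_id"]) == set(p["patient_id"])
        assert not set(alone["patient_id"]) & set(co["patient_id"])

    def test_complete_case_drops_any_missing(self):
        from ceapipe.valuation import DIMENSIONS
        p = self._patients()
        rows = []
        for pid in range(6):
            rows.append([pid, 0] + [1] * 5)
        eq = pd.DataFrame(rows, columns=["patient_id", "visit_month", *DIMENSIONS])
        for d in DIMENSIONS:
            eq[d] = eq[d].astype("Int64")
        eq.loc[eq["patient_id"] == 4, "mobility"] = pd.NA
        out = select_population(p, "complete_case", eq)
        assert 4 not in set(out["patient_id"])
        assert len(out) == 5


class TestHarness:
    def _inputs(self, de=0.0, dc=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        patients = pd.DataFrame({
            "patient_id": range(2 * n),
            "arm": ["control", "intervention"] * n,
            "pp_eligible": [0, 1] * n,
            "death_day": pd.array([pd.NA] * 2 * n, dtype="Int64"),
            "living_alone": rng.integers(0, 2, 2 * n),
        })
        shift = (patients["arm"] == "intervention").to_numpy()
        idx = pd.Index(patients["patient_id"], name="patient_id")
        qalys = pd.DataFrame({
            "qaly_year1": rng.normal(0.8, 0.1, 2 * n) + de * shift / 2,
            "qaly_total_discounted": rng.normal(1.6, 0.2, 2 * n) + de * shift,
        }, index=idx)
        qalys["qaly_year2_undiscounted"] = 0.0
        bundles = pd.DataFrame({
            "societal_total_disc": rng.normal(5e4, 5e3, 2 * n) + dc * shift,
            "societal_total_y1": rng.normal(2.5e4, 3e3, 2 * n) + dc * shift / 2,
            "payer_total_disc": rng.normal(4e4, 4e3, 2 * n) + dc * shift,
            "payer_total_y1": rng.normal(2e4, 2e3, 2 * n),
            "patient_total_disc": rng.normal(2e3, 2e2, 2 * n),
            "patient_total_y1": rng.normal(1e3, 1e2, 2 * n),
        }, index=idx)
        registers = {"patients": patients}
        qalys_by_vs = {"main": {0.03: qalys}, "alt": {0.03: qalys}}
        bundles_by_rate = {0.03: bundles}
        return registers, qalys_by_vs, bundles_by_rate

    def test_duplicate_spec_ids_rejected(self):
        registers, q, b = self._inputs()
        specs = [AnalysisSpec("a", bootstrap_b=10), AnalysisSpec("a", bootstrap_b=10)]
        with pytest.raises(ValueError, match="duplicated"):
            run_harness(registers, specs, q, b)

    def test_null_generator_centres_on_zero(self):
        des, dcs = [], []
        for seed in range(12):
            registers, q, b = self._inputs(seed=seed)
            table, _ = run_harness(
                registers, [AnalysisSpec("main", bootstrap_b=10)], q, b)
            des.append(table.loc[0, "delta_e"])
            dcs.append(table.loc[0, "delta_c"])
        for vals in (des, dcs):
            vals = np.asarray(vals)
            assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_one_year_horizon_uses_year1_columns(self):
        registers, q, b = self._inputs(de=0.2, dc=-5e3, seed=1)
        specs = [AnalysisSpec("h1", horizon_years=1, bootstrap_b=10)]
        table, _ = run_harness(registers, specs, q, b)
        data = pd.DataFrame({
            "arm": registers["patients"].set_index("patient_id")["arm"],
            "q": q["main"][0.03]["qaly_year1"],
            "c": b[0.03]["societal_total_y1"],
        })
        m = data.groupby("arm").mean()
        assert table.loc[0, "delta_e"] == pytest.approx(
            m.loc["intervention", "q"] - m.loc["control", "q"])
        assert table.loc[0, "delta_c"] == pytest.approx(
            m.loc["intervention", "c"] - m.loc["control", "c"])

    def test_perspective_consistency(self):
        # societal dC = payer dC + productivity dC + intervention dC
        registers, q, b = self._inputs(seed=2)
        bundles = b[0.03]
        rng = np.random.default_rng(3)
        prod = rng.normal(1e4, 1e3, len(bundles))
        interv = rng.normal(500, 50, len(bundles))
        bundles["societal_total_disc"] = (
            bundles["payer_total_disc"] + prod + interv)
        specs = [AnalysisSpec("soc", bootstrap_b=10),
                 AnalysisSpec("pay", perspective="payer", bootstrap_b=10)]
        table, _ = run_harness(registers, specs, q, b)
        arm = registers["patients"].set_index("patient_id")["arm"]
        extra = pd.Series(prod + interv, index=bundles.index).groupby(arm).mean()
        gap = extra["intervention"] - extra["control"]
        soc = table.set_index("spec_id").loc["soc", "delta_c"]
        pay = table.set_index("spec_id").loc["pay", "delta_c"]
        assert soc == pytest.approx(pay + gap)

    def test_default_specs_cover_paper_battery(self):
        specs = default_harness_specs()
        ids = {s.spec_id for s in specs}
        assert {"main", "uk_value_set", "discount_5pct", "effects_undiscounted",
                "horizon_1yr", "per_protocol", "complete_case", "survivors_only",
                "living_alone", "cohabiting", "payer_perspective",
                "patient_perspective"} <= ids
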