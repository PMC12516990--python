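# ceapipe

A trial-based cost-effectiveness analysis pipeline for a two-arm RCT with
register-based resource use: synthetic patient registers in, per-perspective
costs and discounted QALYs out, with bootstrapped incremental
cost-effectiveness results and a sensitivity/subgroup harness.

The package is organised around six modules:

| module | what it does |
| --- | --- |
| `ceapipe.synth` | generates synthetic trial registers (stratified 1:1 allocation, EQ-5D-3L trajectories with arm-differential missingness, Poisson care events with DRG weights, dispensations, sick leave, intervention contact logs, deaths) |
| `ceapipe.valuation` | EQ-5D-3L states and value sets (243-state tables), chained-equations multiple imputation on the utility scale with Rubin pooling, trapezoidal QALY accrual with second-year discounting and death handling |
| `ceapipe.costing` | tariff pricing: primary-care visit-form multipliers (1, 0.4, 1.5, 2, 1/3), DRG weight x point-cost pricing with the specialised-outpatient missing-weight fallback, ex-tax drug costs, HCP intervention time, age-banded productivity loss; exact-fraction money, rounded at aggregation |
| `ceapipe.copay` | patient co-payments under ceiling rules: SEK 1150 annual outpatient cap, SEK 100/night with a SEK 1500 cap per 30-consecutive-day window, SEK 2350 annual drug cap, SEK 100 home-visit surcharge |
| `ceapipe.cea` | incremental analysis: within-arm patient-level bootstrap with percentile CIs, dominance classification on the CE plane, baseline group comparisons (t/chi-square/Fisher), and the sensitivity/subgroup harness (alternative value set, 5%/0% discounting, 1-year horizon, per-protocol, complete-case, survivors, living alone/cohabiting, payer/patient perspectives) |
| `ceapipe.report` | end-to-end driver producing demographics, cost and CEA tables, the CE-plane replicate cloud and a JSON summary, deterministically for a fixed seed |

Published value-set coefficient tables are deliberately **not** shipped;
value sets load from user-supplied 243-row CSV files
(`configs/value_set_toy.csv` shows the format) and closed-form synthetic
sets are built in for testing. All tariff and fee amounts in `configs/`
are placeholders.

## CLI

```bash
ceapipe synth --n-per-arm 110 --seed 1 --out scratch/regs
ceapipe value --eq5d scratch/regs/eq5d.csv --patients scratch/regs/patients.csv \
              --mi 20 --discount-effects 0.03 --seed 1 --out scratch/qalys.csv
ceapipe cost  --registers scratch/regs --tariff configs/tariff.yaml --out scratch/bundles.csv
ceapipe copay --registers scratch/regs --rules configs/copay_rules.yaml --out scratch/copay.csv
ceapipe run   --config configs/run.yaml       # full pipeline, all analyses
```

`ceapipe run` writes `table1_demographics.csv`, `table2_costs.csv`,
`table3_cea.csv`, `ce_plane_main.csv`, `copay_by_arm_year.csv`,
`cost_bundles.csv`, `summary.json` and `run.log` into the configured
output directory.

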