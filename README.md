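# prostox-cea

A decision-tree + Markov cohort cost-effectiveness model of toxicity-risk-guided
radiation-therapy selection in prostate cancer, for health-economics analysts and
methodologists who want the published base case, its 5-year cost impact, lifetime
QALY/ICER comparison and uncertainty analyses as tested, reproducible code.

## The model

Patients with prostate cancer recommended for active treatment receive SBRT
(stereotactic body radiation therapy), CFRT (conventionally fractionated
radiotherapy) or prostatectomy. A germline assay classifies each tested patient
as high or low risk for late genitourinary toxicity from SBRT; the risk call
redirects treatment (high risk → CFRT instead of SBRT; low risk → SBRT, with
80% of would-be surgical patients diverted to SBRT). A decision tree allocates
each arm — assay-guided vs standard of care (SOC) — across nine treatment
tracks T1–T9 (risk stratum × modality × arm).

Each track feeds a three-state annual-cycle Markov cohort model
(*no-toxicity* → *toxicity* → *death*), entered at age 67 with everyone
toxicity-free. Per cycle, background mortality q(age) (identical in both
living states) applies first, then survivors at risk develop toxicity with the
track's probability: radiation tracks hold their first-cycle probability p₁
through cycle 4 and taper geometrically (×0.7013/year) thereafter; surgical
tracks can only enter toxicity in cycle 1. Toxicity is absorbing among the
living. Cycle-end state membership accrues that year's cost
(c₀ = \$2,914.90 without, c₁ = \$5,774.58 with toxicity) and utility
(u₀ = 0.90, u₁ = 0.70), discounted at 3%/year. Arm outcomes are
weight-averaged across tracks; the tested arm adds the \$4,000 assay at entry.
Comparisons report ΔC, ΔE, and ICER = ΔC/ΔE — or dominance when one strategy
is both cheaper and more effective.

Uncertainty: a ±20% one-way deterministic sensitivity analysis (tornado) on
5-year savings, and a 10,000-draw probabilistic sensitivity analysis with
moment-matched gamma (costs) and beta (probabilities, utilities) distributions
at 10% SE, summarized on the cost-effectiveness plane and as a
cost-effectiveness acceptability curve (CEAC).

Because no mortality schedule is published, the package generates a synthetic
life table from a Gompertz hazard calibrated to a 16.5-year life expectancy at
age 67 (`prostox_cea.synthetic`); any real life table CSV (`age,q`) can be
substituted.

## Worked example

```python
from prostox_cea import (default_parameters, compute_track_weights,
                         load_printed_table, aggregate_printed_table,
                         compare_arms, default_life_table)

params = default_parameters()
w = compute_track_weights(params, "PROSTOX")
print({t: round(100 * v, 2) for t, v in w.nonzero().items()})
# {'T2': 9.48, 'T3': 9.24, 'T4': 73.26, 'T6': 8.02}

agg = aggregate_printed_table(load_printed_table(), params)
print(round(agg["SOC"]["annual_costs"][4]))        # 1109
print(round(agg["PROSTOX"]["five_year_total"]))    # 47682
print(round(agg["SOC"]["five_year_total"]))        # 67300
print(round(agg["PROSTOX"]["lifetime_qalys"], 2))  # 11.63

cmp = compare_arms(params, default_life_table())
print(round(cmp.cea.delta_cost), round(cmp.cea.delta_qalys, 3), cmp.cea.label)
# -24289 0.204 dominant
```

The first block reproduces the published track weights (9.48% high-risk CFRT,
73.26% low-risk SBRT, …). The second reproduces the published worked-example
aggregation of the per-track outcomes table: a \$1,109 weighted year-5 SOC
cost, 5-year totals of \$47,682 (assay-guided, including the \$4,000 test) vs
\$67,300 (SOC) — \$19,618 saved per tested patient — and 11.63 lifetime QALYs.
The last block runs the full Markov pipeline under the synthetic life table:
assay-guided care costs \$24,289 less and yields 0.204 more QALYs over a
lifetime, a dominant strategy.

## Analysis scripts

The numbered drivers under `analysis/` narrate each stage and write tables
(and figures) under `results/`:

| script | what it does |
|---|---|
| `01_track_weights.py` | decision-tree weights and modality shares per arm |
| `02_five_year_cost_impact.py` | 5-year costs/savings (printed-table and pipeline paths), assay-price sweep |
| `03_lifetime_cea.py` | per-track Markov outcomes, lifetime ΔC/ΔE and dominance |
| `04_dsa_tornado.py` | ±20% one-way sensitivity, tornado ordering |
| `05_psa_ceac.py` | 10,000-draw PSA, CE-plane quadrants, CEAC |

A `prostox-cea` CLI exposes the same stages as subcommands
(`tree`, `markov`, `cost-impact`, `cea`, `dsa`, `psa`, `ceac`,
`make-life-table`, `run-all`); `run-all` writes every artifact plus a
reproducibility manifest.

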