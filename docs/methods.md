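# Methods

## Model structure

The model couples a one-shot decision tree to nine parallel Markov cohort
simulations. The tree splits a tested cohort by predicted late genitourinary
toxicity risk from SBRT (18.72% high risk) and maps each stratum — and the
untested standard-of-care (SOC) comparator — onto treatment tracks:

| track | arm / stratum | modality |
|---|---|---|
| T1–T3 | tested, high risk | SBRT / CFRT / prostatectomy |
| T4–T6 | tested, low risk | SBRT / CFRT / prostatectomy |
| T7–T9 | SOC | SBRT / CFRT / prostatectomy |

With full adherence the high-risk radiation share goes entirely to CFRT and
the low-risk share entirely to SBRT, so T1 and T5 are empty; a
`radiation_adherence` knob generalizes this (a non-adherent patient stays on
the SOC-preferred radiation modality for their stratum — high-risk SBRT, low-risk
CFRT). Low-risk surgical candidates are diverted to SBRT with probability
`surgery_diversion` (default 0.80, taking the prostatectomy share from 49.35%
to 9.87%). Diverted patients go to SBRT, not CFRT, because low-risk patients
have no reason to prefer the longer, costlier modality.

Each track's Markov model has states *no-toxicity*, *toxicity*, *death*;
cycles are one year, entry at age 67 with occupancy (1, 0, 0), and the run
continues to full absorption (terminal life-table age 110, q = 1). Within a
cycle, death is applied first at the age-specific background probability —
identical in both living states, as the model carries no toxicity effect on
survival — and surviving no-toxicity patients then transition with the
track's cycle-specific toxicity probability. Death-before-toxicity is a
competing-risk convention choice; the one-cycle recursion
(1,0,0) → (0.855, 0.095, 0.05) at q = 0.05, p = 0.1 pins it down. Toxicity is
absorbing among the living.

Toxicity hazards: radiation tracks use their first-cycle probability p₁
(T1 0.2778, T4 0.0124, T7 0.0499, CFRT tracks 0.0396) through cycle 4, then
p₁ × 0.7013^(t−4) from cycle 5 — a geometric taper, equivalent to multiplying
the previous cycle's value by the taper each year. Surgical tracks (p₁
0.1189) admit toxicity only in cycle 1.

## Economics

Cycle-end state membership accrues that cycle's full annual cost and utility
(no half-cycle correction; the published per-track magnitudes are consistent
with whole-cycle accrual). Discounting defaults ON at 3%/year for both costs
and utilities with factors (1+d)^(−t), t = 1, 2, …; the one-off treatment
cost falls at entry undiscounted, and the tested arm adds the $4,000 assay
once at entry. The source material is internally contradictory here — its
methods text says discounting was not applied while its input table lists
3.00% discount rates, and the printed lifetime QALYs (~11.6 for a ~16.5-year
life expectancy at 0.9 utility) are only reachable with discounting off if
survival is much longer. We default to the tabulated 3% and expose
`discounting_enabled` for the alternative.

Dominance: a strategy that is strictly cheaper and more effective is reported
as *dominant* (no ICER — negative ratios are ambiguous); the mirror case is
*dominated*; ΔE = 0 leaves the ICER flagged undefined rather than divided.

### Two aggregation paths

The published per-track outcomes table has a quirk: its "annual clinical
costs" cells are the per-patient costs *already multiplied by the track
weight* (e.g. the low-risk SBRT year-1 cell 2135 ≈ 0.7326 × 2914.90), and the
published arm totals multiply those cells by the weights *again*
(1085 × 38.30% + 339 × 12.35% + 1320 × 49.35% = $1,109). The totals
($47,683 / $67,298 / $19,615 savings) are only reachable through exactly that
sum-product, so `aggregate_printed_table` reproduces it verbatim as a
worked-example path, treating the printed cells as inputs. The full pipeline
(`pipeline.compare_arms`) computes genuinely per-patient streams from the
Markov traces instead; its 5-year savings (~$22,200) are larger because true
per-patient annual costs are not shrunk by a second weighting. One published
inconsistency is not modelled: the table lists nonzero lifetime costs but
0.00 QALYs for the zero-weight tracks T1/T5; zero-weight tracks simply drop
out of every aggregation. The published lifetime arm costs
($82,337 / $107,114) are likewise not recoverable from the printed per-track
values and weights (weighted sums disagree by ~0.5%) and are not targeted.

On the fixture path the cumulative savings stay positive every year but
*decline* slightly from the $21,376 entry-cost gap to $19,618 at year 5 —
a direct consequence of the doubly-weighted annual cells; on the full
pipeline they grow monotonically.

## Background mortality

No mortality source or life expectancy is published, so per-track lifetime
values can only be approximated. The synthetic life table uses a Gompertz
hazard h(x) = a·e^(bx) (Makeham constant 0, shape b = 0.095/year — a
realistic old-age doubling time of ~7 years), with the scale `a` found by
bracketed root-finding so that the curtate life expectancy at age 67 equals
16.5 years, a round value consistent with US male period life tables.
Curtate life expectancy (sum of end-of-cycle survival) matches the engine's
whole-cycle accrual. Under this table the per-track discounted lifetime
QALYs land within ~7% of the printed values (10.45–10.84 vs 11.15–11.68) with
the correct ordering by toxicity burden; the incremental comparison is robust
to the target (dominance holds across any plausible life expectancy), which
is why a stand-in is acceptable. Supply a real life-table CSV (`age,q`,
consecutive ages, final q = 1) to replace it.

The microsimulation oracle (`markov.microsimulate`) replays the identical
transition rules patient-by-patient and is used in tests to validate the
cohort recursion within binomial Monte-Carlo error; it is not the production
path.

## Sensitivity analyses

**One-way DSA.** Each input is varied alone to ±20% of its base value
(probabilities and utilities clipped to [0, 1] with a logged warning, e.g.
0.90 × 1.2 → 1.0), the 5-year savings recomputed through the full pipeline,
and parameters ranked by range. Every printed input-table row is its own
parameter: the three SOC utilization shares perturb the SOC arm only (the
other two shares renormalize proportionally; the tested arm's strata are
pinned at base via the `tested_prostatectomy_share` override), and the tested
arm's baseline prostatectomy utilization is a separate parameter. This
row-wise independence mirrors how the inputs are tabulated and reproduces the
published tornado ordering — SOC prostatectomy utilization first
(~$14.1K range), prostatectomy cost a close second (~$12.6K). Under a fully
coupled alternative (tested strata re-derived from the varied SOC share) the
ordering inverts, which is the main reason the row-wise semantics were
chosen. Complement shares (e.g. the 50.65% high-risk CFRT share) are always
re-derived, never varied directly.

**PSA.** 10,000 iterations; each draws every parameter independently from a
moment-matched distribution — gamma (shape = (m/SE)², scale = SE²/m) for
costs, beta (α = m·(m(1−m)/SE² − 1), β = α(1−m)/m) for probabilities and
utilities — with SE = 10% of the mean throughout, since no per-parameter
error data are available. Full adherence (mean 1.0) admits no beta and stays
fixed, as do the discount rates. Draws come from one seeded generator in
parameter-major order, the three SOC shares are renormalized per draw, and
the full pipeline re-runs both arms per iteration with the base-case life
table held fixed. No correlation structure is imposed. A consequence worth
knowing: independent utility draws invert u_notox < u_tox in ≈5% of
iterations, flipping ΔE negative while costs stay negative, so ~94% (not
≥95%) of iterations land in the dominant south-east quadrant; the CEAC is
insensitive to this (≥0.99 across willingness-to-pay $0–150K) because those
draws retain positive net monetary benefit. Quadrant ties go to the adjacent
cost-effective side (ΔC ≤ 0 with ΔE ≥ 0 reads SE).

**Price sweep.** The assay price enters once at entry, so 5-year savings are
exactly affine in it with slope −1; positivity at a $10,000 price follows
from base savings of ~$19.6K at the $4,000 list price.

## Numerical choices and defaults

| parameter | default | note |
|---|---|---|
| cohort entry / size | age 67, 10,000 | cohort fractions make the size immaterial to per-patient results |
| horizon | to age 110 | terminal q = 1 guarantees absorption |
| discount rates | 3%/yr costs & utilities | toggleable |
| DSA delta | ±20% | relative |
| PSA iterations / SE | 10,000 / 10% of mean | seedable |
| WTP | $100,000/QALY | CEAC grid to $150,000 |
| life-table target | 16.5 y at 67 | synthetic stand-in, swappable |

Internal arithmetic is double precision throughout; dollars are rounded only
at reporting. Occupancy conservation is asserted to 1e-9 inside the
recursion. Root-finding uses Brent's method on log-scale with a bracket check
that raises for unreachable life-expectancy targets.

## Limitations

- The synthetic mortality schedule is a calibrated stand-in; absolute
  lifetime costs/QALYs shift with the true life table even though the
  incremental comparison is stable.
- No toxicity-grade stratification, no recovery from late toxicity, no
  cancer progression or cancer-specific mortality, and no effect of toxicity
  on survival — ΔE is driven purely by utility differences.
- The PSA has no correlation structure and applies one blanket 10% SE; real
  parameter uncertainties differ and would change the quadrant fractions.
- The worked-example path inherits the published table's double-weighting
  arithmetic by design; its annual magnitudes are not per-patient costs.
- Synthetic-data tests validate internal consistency, not external validity:
  passing them shows the model reproduces its published arithmetic and
  behaves correctly under its stated assumptions, not that the assay has the
  modelled clinical effect.
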