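"""End-to-end model runs: decision tree -> Markov -> economics for both arms."""

from __future__ import annotations

from dataclasses import dataclass

from .economics import ArmOutcome, CEAResult, TrackOutcome, accumulate_outcomes, \
    aggregate_arm, cost_impact, icer
from .markov import LifeTable, run_cohort
from .params import ARMS, PROSTOX, SOC, ModelParameters
from .synthetic import default_life_table
from .tree import compute_track_weights


@dataclass(frozen=True)
class ArmComparison:
    """Both arms' outcomes plus the incremental comparison (tested vs SOC)."""

    prostox: ArmOutcome
    soc: ArmOutcome
    cea: CEAResult
    five_year_savings: float


def run_track(params: ModelParameters, track: str, life_table: LifeTable) -> TrackOutcome:
    """Markov trace + cost/QALY accrual for one track."""
    trace = run_cohort(params, track, life_table)
    return accumulate_outcomes(trace, params, track)


def arm_outcome(params: ModelParameters, arm: str,
                life_table: LifeTable | None = None) -> ArmOutcome:
    """Full-pipeline outcome for one arm; only weighted tracks are simulated."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    life_table = life_table or default_life_table()
    weights = compute_track_weights(params, arm)
    outcomes = {t: run_track(params, t, life_table) for t in weights.nonzero()}
    return aggregate_arm(outcomes, weights, params)


def compare_arms(params: ModelParameters,
                 life_table: LifeTable | None = None,
                 horizon_years: int = 5) -> ArmComparison:
    """Run both arms through the full pipeline and compare them."""
    life_table = life_table or default_life_table()
    a = arm_outcome(params, PROSTOX, life_table)
    b = arm_outcome(params, SOC, life_table)
    impact = cost_impact(a, b, horizon_years)
    return ArmComparison(
        prostox=a, soc=b,
        cea=icer(a, b, wtp=params.wtp_default),
        five_year_savings=float(impact["cumulative_savings"][-1]),
    )


def five_year_savings(params: ModelParameters,
                      life_table: LifeTable | None = None) -> float:
    """Cumulative 5-year savings per tested patient (tested arm vs SOC)."""
    return compare_arms(params, life_table).five_year_savings
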