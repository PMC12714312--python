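"""Costs, QALYs, arm aggregation, 5-year cost impact, ICER and the price sweep.

Two aggregation paths coexist deliberately:

* the *full pipeline* (:func:`accumulate_outcomes` + :func:`aggregate_arm`)
  turns Markov traces into genuinely per-patient discounted cost and QALY
  streams and weights them by track;
* the *worked-example path* (:func:`aggregate_printed_table`) reproduces the
  published table arithmetic on the printed per-track cells. The published
  annual-cost cells are already scaled by track weight, and the published
  totals multiply them by the weights once more; this path applies exactly
  that sum-product so the printed five-year totals are recovered to the
  dollar. It exists for worked-example reproduction, not as the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .markov import CohortTrace
from .params import (
    PROSTOX, SOC, TRACK_MODALITY, ModelParameters, PrintedTrackTable,
)
from .tree import TrackWeights

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADEOFF = "tradeoff"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class TrackOutcome:
    """Per-patient discounted outcomes for one track."""

    track: str
    treatment_cost: float          # one-off cost at model entry
    annual_costs: np.ndarray       # clinical cost accrued in cycles 1..T
    annual_qalys: np.ndarray       # QALYs accrued in cycles 1..T
    lifetime_cost: float
    lifetime_qalys: float


@dataclass(frozen=True)
class ArmOutcome:
    """Weighted aggregation of track outcomes for one arm."""

    arm: str
    t0_cost: float                 # weighted treatment cost (+ test for the tested arm)
    annual_costs: np.ndarray       # weighted clinical cost stream, cycles 1..T
    cumulative_costs: np.ndarray   # index k = cumulative cost through year k (index 0 = T0)
    lifetime_cost: float
    lifetime_qalys: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness comparison of two strategies."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str                     # dominant | dominated | tradeoff | undefined
    wtp: float

    @property
    def cost_effective(self) -> bool:
        if self.label == DOMINANT:
            return True
        if self.label == DOMINATED:
            return False
        return self.wtp * self.delta_qalys - self.delta_cost >= 0


def _discount_factors(n: int, rate: float, enabled: bool) -> np.ndarray:
    t = np.arange(1, n + 1, dtype=float)
    if not enabled:
        return np.ones(n)
    return (1.0 + rate) ** -t


def accumulate_outcomes(trace: CohortTrace, params: ModelParameters,
                        track: str) -> TrackOutcome:
    """Attach costs and QALYs to a cohort trace.

    State membership at the end of cycle t accrues that cycle's full annual
    cost and utility (no half-cycle correction), discounted by
    (1+d)^-t when discounting is enabled. The one-off treatment cost falls
    at model entry and is never discounted.
    """
    n = trace.n_cycles
    notox, tox = trace.notox[1:], trace.tox[1:]
    cost_raw = notox * params.c_notox + tox * params.c_tox
    qaly_raw = notox * params.u_notox + tox * params.u_tox
    costs = cost_raw * _discount_factors(n, params.d_cost, params.discounting_enabled)
    qalys = qaly_raw * _discount_factors(n, params.d_util, params.discounting_enabled)
    treatment = params.c_treat[TRACK_MODALITY[track]]
    return TrackOutcome(
        track=track,
        treatment_cost=treatment,
        annual_costs=costs,
        annual_qalys=qalys,
        lifetime_cost=treatment + float(costs.sum()),
        lifetime_qalys=float(qalys.sum()),
    )


def aggregate_arm(track_outcomes: Mapping[str, TrackOutcome], weights: TrackWeights,
                  params: ModelParameters) -> ArmOutcome:
    """Weight track outcomes into an arm-level outcome.

    Only tracks with nonzero weight need outcomes. The tested arm adds the
    assay cost once at model entry.
    """
    active = weights.nonzero()
    missing = set(active) - set(track_outcomes)
    if missing:
        raise ValueError(f"missing outcomes for weighted tracks: {sorted(missing)}")
    n = max((len(track_outcomes[t].annual_costs) for t in active), default=0)
    costs = np.zeros(n)
    qalys = np.zeros(n)
    t0 = 0.0
    for track, w in active.items():
        out = track_outcomes[track]
        costs[:len(out.annual_costs)] += w * out.annual_costs
        qalys[:len(out.annual_qalys)] += w * out.annual_qalys
        t0 += w * out.treatment_cost
    if weights.arm == PROSTOX:
        t0 += params.c_test
    cumulative = t0 + np.concatenate([[0.0], np.cumsum(costs)])
    return ArmOutcome(
        arm=weights.arm,
        t0_cost=t0,
        annual_costs=costs,
        cumulative_costs=cumulative,
        lifetime_cost=float(cumulative[-1]),
        lifetime_qalys=float(qalys.sum()),
    )


def aggregate_printed_table(fixture: PrintedTrackTable,
                            params: ModelParameters) -> dict[str, dict]:
    """Reproduce the published sum-product aggregation of the printed table.

    For each arm: weighted year-k cost = sum over tracks of weight x printed
    year-k cell; the five-year cumulative adds the weighted treatment costs
    (plus the assay cost for the tested arm); lifetime QALYs are the weighted
    printed per-track QALYs (zero-weight tracks drop out automatically).
    """
    results: dict[str, dict] = {}
    for arm in (PROSTOX, SOC):
        rows = fixture.arm_rows(arm)
        w = rows["weight_pct"].to_numpy() / 100.0
        annual = np.array([(rows[f"cost_y{k}"].to_numpy() * w).sum() for k in range(1, 6)])
        t0 = float((rows["cost_t0"].to_numpy() * w).sum())
        if arm == PROSTOX:
            t0 += params.c_test
        cumulative = t0 + np.concatenate([[0.0], np.cumsum(annual)])
        results[arm] = {
            "t0_cost": t0,
            "annual_costs": annual,
            "cumulative_costs": cumulative,
            "five_year_total": float(cumulative[-1]),
            "lifetime_qalys": float((rows["lifetime_qalys"].to_numpy() * w).sum()),
        }
    return results


def printed_table_arm_outcomes(fixture: PrintedTrackTable,
                               params: ModelParameters) -> dict[str, ArmOutcome]:
    """Worked-example aggregates wrapped as :class:`ArmOutcome` (5-year horizon)."""
    agg = aggregate_printed_table(fixture, params)
    out = {}
    for arm, a in agg.items():
        out[arm] = ArmOutcome(
            arm=arm, t0_cost=a["t0_cost"], annual_costs=a["annual_costs"],
            cumulative_costs=a["cumulative_costs"],
            lifetime_cost=a["five_year_total"], lifetime_qalys=a["lifetime_qalys"],
        )
    return out


def cost_impact(arm_a: ArmOutcome, arm_b: ArmOutcome,
                horizon_years: int) -> dict[str, np.ndarray]:
    """Per-year and cumulative savings of strategy A relative to B.

    Savings at year k = B's cumulative cost - A's cumulative cost; positive
    numbers favour A.
    """
    for arm in (arm_a, arm_b):
        if len(arm.cumulative_costs) - 1 < horizon_years:
            raise ValueError(f"{arm.arm} stream covers {len(arm.cumulative_costs) - 1} "
                             f"years < horizon {horizon_years}")
    years = np.arange(horizon_years + 1)
    cum_a = arm_a.cumulative_costs[:horizon_years + 1]
    cum_b = arm_b.cumulative_costs[:horizon_years + 1]
    return {
        "year": years,
        "cumulative_a": cum_a,
        "cumulative_b": cum_b,
        "cumulative_savings": cum_b - cum_a,
        "annual_savings": np.diff(cum_b - cum_a, prepend=0.0) + 0.0,
    }


def icer(arm_a: ArmOutcome, arm_b: ArmOutcome, wtp: float = 100_000.0) -> CEAResult:
    """Incremental cost-effectiveness of A vs B, with dominance classification.

    A negative ICER is never reported: strictly cheaper and more effective is
    "dominant", costlier and less effective "dominated". A zero QALY
    difference leaves the ICER undefined (flagged, no division).
    """
    d_cost = arm_a.lifetime_cost - arm_b.lifetime_cost
    d_qaly = arm_a.lifetime_qalys - arm_b.lifetime_qalys
    if d_qaly == 0.0:
        return CEAResult(d_cost, d_qaly, None, UNDEFINED, wtp)
    if d_cost < 0 and d_qaly > 0:
        return CEAResult(d_cost, d_qaly, None, DOMINANT, wtp)
    if d_cost > 0 and d_qaly < 0:
        return CEAResult(d_cost, d_qaly, None, DOMINATED, wtp)
    return CEAResult(d_cost, d_qaly, d_cost / d_qaly, TRADEOFF, wtp)


def price_threshold_sweep(prices: Iterable[float], base_savings: float,
                          base_test_cost: float) -> dict[float, float]:
    """Five-year savings as a function of assay price.

    The assay cost enters the tested arm exactly once at model entry, so
    savings are affine in the price with slope -1:
    savings(p) = savings(base price) - (p - base price).
    """
    out = {}
    for p in prices:
        if p < 0:
            raise ValueError(f"price must be >= 0, got {p}")
        out[float(p)] = base_savings - (float(p) - base_test_cost)
    return out
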