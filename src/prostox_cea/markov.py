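"""Three-state Markov cohort engine: no-toxicity, toxicity, death.

One cycle is one year. All patients enter in the no-toxicity state. Each
cycle, background mortality (identical in both living states — the model
carries no toxicity effect on survival) is applied first; surviving
no-toxicity patients may then develop late toxicity. Toxicity is absorbing
among the living: once developed, its management costs and quality-of-life
decrement persist until death. Death is absorbing.

Radiation tracks keep their first-cycle toxicity probability through cycle 4;
from cycle 5 a geometric taper multiplies it each year. Surgical tracks can
only enter the toxicity state in cycle 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import PROSTATECTOMY, TRACK_MODALITY, TRACKS, ModelParameters

_OCC_TOL = 1e-12


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities, terminal q = 1.

    Ages increase in steps of one year; the final entry must have q = 1 so
    the cohort is guaranteed to be absorbed into the death state.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != q.shape:
            raise ValueError("life table requires matching 1-D age and q arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life-table ages must increase in steps of 1 year")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("life-table death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ValueError("life table must end with q = 1 (guarantees absorption)")

    def q_at(self, age: int) -> float:
        """Annual death probability at ``age``; 1 beyond the terminal age."""
        if age < self.ages[0]:
            raise ValueError(f"age {age} precedes life-table start {self.ages[0]}")
        if age > self.ages[-1]:
            return 1.0
        return float(self.q[age - self.ages[0]])

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "q": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        frame = pd.read_csv(path)
        if not {"age", "q"} <= set(frame.columns):
            raise ValueError("life-table CSV needs columns 'age' and 'q'")
        return cls(ages=frame["age"].to_numpy(), q=frame["q"].to_numpy())


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one track's cohort.

    Index 0 is model entry (everyone in no-toxicity); occupancies at every
    cycle sum to one, and both death occupancy and cumulative toxicity
    incidence are non-decreasing.
    """

    track: str
    notox: np.ndarray
    tox: np.ndarray
    dead: np.ndarray
    cum_tox: np.ndarray  # cumulative toxicity incidence

    def __post_init__(self) -> None:
        for name in ("notox", "tox", "dead", "cum_tox"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_cycles(self) -> int:
        return len(self.notox) - 1

    def alive(self) -> np.ndarray:
        return self.notox + self.tox

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self.notox)),
            "notox": self.notox, "tox": self.tox, "dead": self.dead,
            "cum_tox": self.cum_tox,
        })


def toxicity_probability(params: ModelParameters, track: str, cycle: int) -> float:
    """No-toxicity -> toxicity transition probability for ``track`` at ``cycle`` (1-based)."""
    if track not in TRACKS:
        raise ValueError(f"unknown track {track!r}")
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    p1 = params.tox_p1[track]
    if TRACK_MODALITY[track] == PROSTATECTOMY:
        return p1 if cycle == 1 else 0.0
    if cycle <= 4:
        return p1
    return min(1.0, p1 * params.taper ** (cycle - 4))


def run_cohort(params: ModelParameters, track: str, life_table: LifeTable,
               max_cycles: int | None = None) -> CohortTrace:
    """Deterministic cohort recursion for one track.

    Runs until the cohort is fully absorbed into death (the life table's
    terminal q = 1 bounds the horizon) or for ``max_cycles`` cycles.
    """
    if params.start_age < life_table.ages[0]:
        raise ValueError("cohort start age precedes the life table")
    horizon = life_table.terminal_age - params.start_age + 1
    if max_cycles is not None:
        horizon = min(horizon, max_cycles)
    if horizon < 1:
        raise ValueError("horizon must allow at least one cycle")

    notox = np.empty(horizon + 1)
    tox = np.empty(horizon + 1)
    dead = np.empty(horizon + 1)
    cum_tox = np.empty(horizon + 1)
    notox[0], tox[0], dead[0], cum_tox[0] = 1.0, 0.0, 0.0, 0.0

    for t in range(1, horizon + 1):
        q = life_table.q_at(params.start_age + t - 1)
        p = toxicity_probability(params, track, t)
        surv_notox = notox[t - 1] * (1.0 - q)
        surv_tox = tox[t - 1] * (1.0 - q)
        new_tox = surv_notox * p
        notox[t] = surv_notox - new_tox
        tox[t] = surv_tox + new_tox
        dead[t] = dead[t - 1] + (notox[t - 1] + tox[t - 1]) * q
        cum_tox[t] = cum_tox[t - 1] + new_tox
        assert abs(notox[t] + tox[t] + dead[t] - 1.0) < 1e-9

    return CohortTrace(track=track, notox=notox, tox=tox, dead=dead, cum_tox=cum_tox)


def microsimulate(params: ModelParameters, track: str, life_table: LifeTable,
                  n: int, seed: int, max_cycles: int | None = None) -> CohortTrace:
    """Patient-level Monte-Carlo oracle for :func:`run_cohort`.

    Simulates ``n`` independent patients under the identical transition rules
    (death applied before toxicity within a cycle) and returns the empirical
    occupancy trace. Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    horizon = life_table.terminal_age - params.start_age + 1
    if max_cycles is not None:
        horizon = min(horizon, max_cycles)

    NOTOX, TOX, DEAD = 0, 1, 2
    state = np.zeros(n, dtype=np.int8)
    ever_tox = np.zeros(n, dtype=bool)
    notox = np.empty(horizon + 1)
    tox = np.empty(horizon + 1)
    dead = np.empty(horizon + 1)
    cum_tox = np.empty(horizon + 1)
    notox[0], tox[0], dead[0], cum_tox[0] = 1.0, 0.0, 0.0, 0.0

    for t in range(1, horizon + 1):
        q = life_table.q_at(params.start_age + t - 1)
        p = toxicity_probability(params, track, t)
        alive = state != DEAD
        dies = alive & (rng.random(n) < q)
        state[dies] = DEAD
        at_risk = (state == NOTOX)
        develops = at_risk & (rng.random(n) < p)
        state[develops] = TOX
        ever_tox |= develops
        notox[t] = np.mean(state == NOTOX)
        tox[t] = np.mean(state == TOX)
        dead[t] = np.mean(state == DEAD)
        cum_tox[t] = np.mean(ever_tox)

    return CohortTrace(track=track, notox=notox, tox=tox, dead=dead, cum_tox=cum_tox)
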