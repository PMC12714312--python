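"""Synthetic inputs: a calibrated background-mortality life table and
randomized parameter sets for property testing.

The published model never states its mortality source, so the package ships a
parametric stand-in: a Gompertz-Makeham hazard, calibrated by root-finding so
that the undiscounted life expectancy at the cohort entry age matches a
target (default 16.5 years at age 67, a round figure consistent with US male
period life tables). Outputs built from it are labelled synthetic; a real
life-table CSV can be supplied anywhere a LifeTable is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .markov import LifeTable
from .params import MODALITIES, ModelParameters, default_parameters

DEFAULT_TARGET_LE = 16.5
DEFAULT_START_AGE = 67
DEFAULT_GOMPERTZ_SHAPE = 0.095
TERMINAL_AGE = 110


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(x) = lam + a * exp(b * x); annual q(x) = 1 - exp(-h(x))."""

    lam: float = 0.0
    a: float = 5e-5
    b: float = DEFAULT_GOMPERTZ_SHAPE
    terminal_age: int = TERMINAL_AGE

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("Makeham constant lam must be >= 0")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gompertz scale a and shape b must be > 0")

    def annual_q(self, age: np.ndarray) -> np.ndarray:
        hazard = self.lam + self.a * np.exp(self.b * np.asarray(age, dtype=float))
        return 1.0 - np.exp(-hazard)


def generate_life_table(gm: GompertzMakehamParams, start_age: int) -> LifeTable:
    """Life table from ``start_age`` to the terminal age; final q forced to 1."""
    if start_age >= gm.terminal_age:
        raise ValueError("start age must precede the terminal age")
    ages = np.arange(start_age, gm.terminal_age + 1)
    q = np.clip(gm.annual_q(ages), 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(ages=ages, q=q)


def life_expectancy(table: LifeTable, start_age: int | None = None) -> float:
    """Curtate life expectancy: sum over cycles of survival to cycle end.

    Matches the Markov engine's whole-cycle accounting (a year is lived iff
    the patient is alive at that cycle's end).
    """
    start_age = table.ages[0] if start_age is None else start_age
    if start_age < table.ages[0]:
        raise ValueError("start age precedes the life table")
    q = table.q[start_age - table.ages[0]:]
    survival = np.cumprod(1.0 - q)
    return float(survival.sum())


def calibrate_life_table(target_le: float = DEFAULT_TARGET_LE,
                         start_age: int = DEFAULT_START_AGE,
                         b: float = DEFAULT_GOMPERTZ_SHAPE,
                         terminal_age: int = TERMINAL_AGE) -> LifeTable:
    """Find the Gompertz scale ``a`` whose life expectancy at ``start_age``
    equals ``target_le`` (lam fixed at 0, shape ``b`` fixed). Deterministic.
    """

    def le_of(log_a: float) -> float:
        gm = GompertzMakehamParams(lam=0.0, a=np.exp(log_a), b=b, terminal_age=terminal_age)
        return life_expectancy(generate_life_table(gm, start_age))

    lo, hi = np.log(1e-10), np.log(1.0)
    if not (le_of(hi) <= target_le <= le_of(lo)):
        raise ValueError(f"target life expectancy {target_le} outside the achievable "
                         f"range [{le_of(hi):.2f}, {le_of(lo):.2f}] years")
    log_a = brentq(lambda x: le_of(x) - target_le, lo, hi, xtol=1e-12)
    table = generate_life_table(
        GompertzMakehamParams(lam=0.0, a=float(np.exp(log_a)), b=b,
                              terminal_age=terminal_age), start_age)
    achieved = life_expectancy(table)
    assert abs(achieved - target_le) <= 0.1, achieved
    return table


@lru_cache(maxsize=1)
def default_life_table() -> LifeTable:
    """The package's default synthetic mortality schedule (16.5 y LE at 67)."""
    return calibrate_life_table()


def random_parameter_set(seed: int, jitter: float = 0.2) -> ModelParameters:
    """Defaults perturbed multiplicatively by uniform +/- ``jitter``.

    Probabilities are clipped to [0, 1] and the utilization shares
    renormalized, so the result always validates. Property-test fuel.
    """
    if not 0.0 <= jitter <= 0.5:
        raise ValueError("jitter must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    base = default_parameters()

    def j(x: float, lo: float = 0.0, hi: float | None = None) -> float:
        y = x * (1.0 + rng.uniform(-jitter, jitter))
        if hi is not None:
            y = min(y, hi)
        return max(y, lo)

    shares = np.array([j(base.soc_utilization[m]) for m in MODALITIES])
    shares = shares / shares.sum()
    return ModelParameters(
        p_high=j(base.p_high, hi=1.0),
        soc_utilization=dict(zip(MODALITIES, shares.tolist())),
        surgery_diversion=j(base.surgery_diversion, hi=1.0),
        radiation_adherence=j(base.radiation_adherence, hi=1.0),
        tox_p1={t: j(p, hi=1.0) for t, p in base.tox_p1.items()},
        taper=min(max(j(base.taper), 1e-6), 1.0),
        u_notox=j(base.u_notox, hi=1.0),
        u_tox=j(base.u_tox, hi=1.0),
        d_cost=j(base.d_cost),
        d_util=j(base.d_util),
        c_treat={m: j(c) for m, c in base.c_treat.items()},
        c_test=j(base.c_test),
        c_notox=j(base.c_notox),
        c_tox=j(base.c_tox),
    )
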