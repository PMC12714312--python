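"""Uncertainty analyses: one-way deterministic sensitivity (tornado),
probabilistic sensitivity with gamma/beta moment matching, cost-effectiveness
plane quadrants, and the acceptability curve.

Parameter semantics follow the published input table row by row: every
printed input is one sensitivity parameter. In particular the three
standard-of-care utilization shares are varied within the SOC arm only
(the other two shares renormalize proportionally), while the tested arm's
baseline prostatectomy utilization is its own parameter — the two arms'
printed rows are independent inputs even though their base values coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markov import LifeTable
from .params import CFRT, MODALITIES, PROSTATECTOMY, SBRT, ModelParameters
from .pipeline import compare_arms, five_year_savings
from .synthetic import default_life_table

logger = logging.getLogger(__name__)

NE, SE, SW, NW = "NE", "SE", "SW", "NW"

# Track groups sharing one printed first-cycle toxicity probability
_TOX_GROUPS = {
    "tox_p1_sbrt_high_risk": ("T1",),
    "tox_p1_cfrt": ("T2", "T5", "T8"),
    "tox_p1_prostatectomy": ("T3", "T6", "T9"),
    "tox_p1_sbrt_low_risk": ("T4",),
    "tox_p1_sbrt_soc": ("T7",),
}


def _clip01(name: str, value: float) -> float:
    if value > 1.0 or value < 0.0:
        logger.warning("%s perturbed to %.4f; clipped into [0, 1]", name, value)
        return min(max(value, 0.0), 1.0)
    return value


@dataclass(frozen=True)
class ParameterDef:
    """One sensitivity parameter: base value plus an applier that writes a
    new value into a parameter dump (mutating it in place)."""

    name: str
    kind: str  # cost | probability | utility | rate
    get: Callable[[ModelParameters], float]
    apply: Callable[[dict, float], None]


def _scalar(name: str, kind: str, field: str) -> ParameterDef:
    return ParameterDef(name, kind, lambda p, f=field: getattr(p, f),
                        lambda d, v, f=field: d.__setitem__(f, v))


def _nested(name: str, kind: str, field: str, key: str) -> ParameterDef:
    return ParameterDef(name, kind, lambda p, f=field, k=key: getattr(p, f)[k],
                        lambda d, v, f=field, k=key: d[f].__setitem__(k, v))


def _tox_group(name: str, tracks: tuple[str, ...]) -> ParameterDef:
    def apply(d: dict, v: float, tracks=tracks) -> None:
        for t in tracks:
            d["tox_p1"][t] = v
    return ParameterDef(name, "probability",
                        lambda p, t=tracks[0]: p.tox_p1[t], apply)


def _soc_share(name: str, modality: str) -> ParameterDef:
    """Vary one SOC utilization share; renormalize the other two
    proportionally; pin the tested arm's baseline so only the SOC arm moves."""

    def apply(d: dict, v: float, modality=modality) -> None:
        shares = d["soc_utilization"]
        if d.get("tested_prostatectomy_share") is None:
            d["tested_prostatectomy_share"] = shares[PROSTATECTOMY]
        old = shares[modality]
        v = min(v, 1.0)
        rest = 1.0 - old
        scale = (1.0 - v) / rest if rest > 0 else 0.0
        for m in MODALITIES:
            shares[m] = v if m == modality else shares[m] * scale

    return ParameterDef(name, "probability",
                        lambda p, m=modality: p.soc_utilization[m], apply)


def _tested_prostatectomy() -> ParameterDef:
    def apply(d: dict, v: float) -> None:
        d["tested_prostatectomy_share"] = v
    return ParameterDef("tested_prostatectomy_share", "probability",
                        lambda p: p.prostatectomy_share_tested(), apply)


def parameter_definitions() -> list[ParameterDef]:
    """Every model input varied in the sensitivity analyses."""
    defs = [
        _scalar("p_high", "probability", "p_high"),
        _soc_share("soc_sbrt_utilization", SBRT),
        _soc_share("soc_cfrt_utilization", CFRT),
        _soc_share("soc_prostatectomy_utilization", PROSTATECTOMY),
        _tested_prostatectomy(),
        _scalar("surgery_diversion", "probability", "surgery_diversion"),
        _scalar("radiation_adherence", "probability", "radiation_adherence"),
        _scalar("taper", "probability", "taper"),
        _scalar("u_notox", "utility", "u_notox"),
        _scalar("u_tox", "utility", "u_tox"),
        _scalar("d_cost", "rate", "d_cost"),
        _scalar("d_util", "rate", "d_util"),
        _nested("c_sbrt", "cost", "c_treat", SBRT),
        _nested("c_cfrt", "cost", "c_treat", CFRT),
        _nested("c_prostatectomy", "cost", "c_treat", PROSTATECTOMY),
        _scalar("c_test", "cost", "c_test"),
        _scalar("c_notox", "cost", "c_notox"),
        _scalar("c_tox", "cost", "c_tox"),
    ]
    defs[8:8] = [_tox_group(name, tracks) for name, tracks in _TOX_GROUPS.items()]
    return defs


def _perturbed(params: ModelParameters, pdef: ParameterDef, value: float) -> ModelParameters:
    d = params.model_dump()
    if pdef.kind in ("probability", "utility"):
        value = _clip01(pdef.name, value)
    pdef.apply(d, value)
    return ModelParameters(**d)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DsaResult:
    """Tornado table: per parameter the low/high outcomes and range width,
    sorted by descending range."""

    base_outcome: float
    delta: float
    table: pd.DataFrame  # columns: parameter, base_value, low, high, range

    def top_parameter(self) -> str:
        return str(self.table.iloc[0]["parameter"])


def run_dsa(params: ModelParameters, delta: float | None = None,
            outcome: Callable[[ModelParameters], float] | None = None,
            life_table: LifeTable | None = None) -> DsaResult:
    """Vary each parameter alone by +/- ``delta`` (relative) and recompute the
    outcome through the full pipeline; default outcome is 5-year savings."""
    delta = params.dsa_delta if delta is None else delta
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"delta must lie in [0, 1), got {delta}")
    life_table = life_table or default_life_table()
    if outcome is None:
        outcome = lambda p: five_year_savings(p, life_table)
    base = outcome(params)
    rows = []
    for pdef in parameter_definitions():
        v0 = pdef.get(params)
        low = outcome(_perturbed(params, pdef, v0 * (1.0 - delta)))
        high = outcome(_perturbed(params, pdef, v0 * (1.0 + delta)))
        rows.append({"parameter": pdef.name, "base_value": v0,
                     "low": low, "high": high,
                     "range": abs(high - low)})
    table = pd.DataFrame(rows).sort_values("range", ascending=False,
                                           kind="mergesort").reset_index(drop=True)
    return DsaResult(base_outcome=base, delta=delta, table=table)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

GAMMA, BETA, FIXED = "gamma", "beta", "fixed"


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter: gamma for costs, beta for
    probabilities and utilities, fixed for degenerate inputs."""

    name: str
    family: str
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.family not in (GAMMA, BETA, FIXED):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != FIXED and self.se <= 0:
            raise ValueError(f"{self.name}: SE must be > 0 for {self.family}")
        if self.family == BETA and not 0.0 < self.mean < 1.0:
            raise ValueError(f"{self.name}: beta requires mean in (0, 1), got {self.mean}")


class _PointMass:
    def __init__(self, value: float):
        self.value = value

    def rvs(self, size: int, random_state=None) -> np.ndarray:
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0


def calibrate_distribution(spec: DistributionSpec):
    """Moment-match a frozen distribution to the spec's mean and SE.

    gamma: shape = (mean/SE)^2, scale = SE^2/mean.
    beta:  alpha = mean * (mean(1-mean)/SE^2 - 1), beta = alpha (1-mean)/mean.
    """
    if spec.family == FIXED:
        return _PointMass(spec.mean)
    if spec.family == GAMMA:
        if spec.mean <= 0:
            return _PointMass(spec.mean)
        shape = (spec.mean / spec.se) ** 2
        scale = spec.se ** 2 / spec.mean
        return stats.gamma(a=shape, scale=scale)
    # beta
    var = spec.se ** 2
    if var >= spec.mean * (1.0 - spec.mean):
        raise ValueError(f"{spec.name}: beta variance {var:.4g} infeasible for "
                         f"mean {spec.mean} (must be < mean(1-mean))")
    nu = spec.mean * (1.0 - spec.mean) / var - 1.0
    alpha = spec.mean * nu
    return stats.beta(a=alpha, b=alpha * (1.0 - spec.mean) / spec.mean)


def default_psa_specs(params: ModelParameters) -> list[DistributionSpec]:
    """One spec per sensitivity parameter: gamma for costs, beta for
    probabilities and utilities, 10% SE default; inputs whose beta moments
    are infeasible (e.g. full adherence, mean 1) and discount rates stay fixed."""
    se_frac = params.psa_default_se_frac
    specs = []
    for pdef in parameter_definitions():
        mean = pdef.get(params)
        if pdef.kind == "cost":
            family, se = GAMMA, se_frac * mean
        elif pdef.kind in ("probability", "utility"):
            if mean <= 0.0 or mean >= 1.0:
                family, se = FIXED, 0.0
            else:
                family, se = BETA, se_frac * mean
                if se ** 2 >= mean * (1.0 - mean):
                    family, se = FIXED, 0.0
        else:  # discount rates held fixed
            family, se = FIXED, 0.0
        specs.append(DistributionSpec(pdef.name, family, mean, se))
    return specs


def classify_quadrant(d_cost: float, d_qaly: float) -> str:
    """Cost-effectiveness plane quadrant; boundary values join the adjacent
    cost-effective side (so (0, 0) reads as SE, 'no worse on either axis')."""
    if d_cost <= 0 and d_qaly >= 0:
        return SE
    if d_cost > 0 and d_qaly > 0:
        return NE
    if d_cost <= 0 and d_qaly < 0:
        return SW
    return NW


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration incremental outcomes of the probabilistic analysis."""

    n: int
    seed: int
    frame: pd.DataFrame  # iteration, delta_cost, delta_qaly, quadrant

    def quadrant_fractions(self) -> pd.Series:
        return self.frame["quadrant"].value_counts(normalize=True)


def run_psa(params: ModelParameters, specs: Sequence[DistributionSpec] | None = None,
            n: int | None = None, seed: int = 0,
            life_table: LifeTable | None = None) -> PsaResult:
    """Monte-Carlo re-evaluation of the full pipeline.

    All parameters are drawn independently from their calibrated
    distributions (parameter-major draw order from one seeded generator),
    the utilization shares renormalized per draw, and the decision tree,
    Markov engine and economics re-run for both arms each iteration. The
    base-case life table is held fixed across iterations.
    """
    n = params.psa_iterations if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = default_psa_specs(params) if specs is None else list(specs)
    life_table = life_table or default_life_table()
    rng = np.random.default_rng(seed)

    defs = {p.name: p for p in parameter_definitions()}
    draws: dict[str, np.ndarray] = {}
    for spec in specs:  # parameter-major, iteration-minor
        if spec.name not in defs:
            raise ValueError(f"spec for unknown parameter {spec.name!r}")
        draws[spec.name] = calibrate_distribution(spec).rvs(size=n, random_state=rng)

    share_names = {f"soc_{m}_utilization": m for m in MODALITIES}
    records = []
    for i in range(n):
        d = params.model_dump()
        if d.get("tested_prostatectomy_share") is None:
            d["tested_prostatectomy_share"] = d["soc_utilization"][PROSTATECTOMY]
        for name, values in draws.items():
            v = float(values[i])
            pdef = defs[name]
            if pdef.kind in ("probability", "utility"):
                v = min(max(v, 0.0), 1.0)
            if name in share_names:
                d["soc_utilization"][share_names[name]] = v
            else:
                pdef.apply(d, v)
        total = sum(d["soc_utilization"].values())
        d["soc_utilization"] = {m: s / total for m, s in d["soc_utilization"].items()}
        cmp = compare_arms(ModelParameters(**d), life_table)
        dc, de = cmp.cea.delta_cost, cmp.cea.delta_qalys
        records.append((i, dc, de, classify_quadrant(dc, de)))

    frame = pd.DataFrame(records, columns=["iteration", "delta_cost",
                                           "delta_qaly", "quadrant"])
    return PsaResult(n=n, seed=seed, frame=frame)


# ---------------------------------------------------------------------------
# Cost-effectiveness acceptability curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CeacCurve:
    """Probability the tested strategy is cost-effective at each WTP."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(psa: PsaResult, wtp_grid: Iterable[float]) -> CeacCurve:
    """At each willingness-to-pay lambda, the fraction of iterations with
    non-negative net monetary benefit lambda * dE - dC."""
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if np.any(wtp < 0) or np.any(np.diff(wtp) <= 0):
        raise ValueError("WTP grid must be non-negative and strictly increasing")
    dc = psa.frame["delta_cost"].to_numpy()
    de = psa.frame["delta_qaly"].to_numpy()
    nmb = wtp[:, None] * de[None, :] - dc[None, :]
    return CeacCurve(wtp=wtp, probability=(nmb >= 0).mean(axis=1))
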