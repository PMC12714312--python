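"""Model parameters: definition, validation, load/save, and the printed per-track table.

The parameter set collects every clinical and economic input of the model:
the fraction of tested patients called high risk, treatment-utilization
shares, per-track first-cycle toxicity probabilities, the multiplicative
toxicity taper from cycle 5 onward, health-state utilities, annual
management costs, one-off treatment costs, the assay list price, discount
rates, and the simulation/scenario knobs (cohort size, start age, PSA and
DSA settings, adherence and surgery diversion).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

# Treatment modalities
SBRT = "sbrt"
CFRT = "cfrt"
PROSTATECTOMY = "prostatectomy"
MODALITIES = (SBRT, CFRT, PROSTATECTOMY)

# The nine decision-tree end nodes ("tracks"):
# T1-T3 tested high risk (SBRT / CFRT / prostatectomy),
# T4-T6 tested low risk, T7-T9 standard of care.
TRACKS = tuple(f"T{i}" for i in range(1, 10))
PROSTOX_TRACKS = ("T1", "T2", "T3", "T4", "T5", "T6")
SOC_TRACKS = ("T7", "T8", "T9")

TRACK_MODALITY = {
    "T1": SBRT, "T2": CFRT, "T3": PROSTATECTOMY,
    "T4": SBRT, "T5": CFRT, "T6": PROSTATECTOMY,
    "T7": SBRT, "T8": CFRT, "T9": PROSTATECTOMY,
}

PROSTOX = "PROSTOX"
SOC = "SOC"
ARMS = (PROSTOX, SOC)

_SHARE_TOL = 1e-9


class ModelParameters(BaseModel):
    """Validated parameter set for the hybrid decision-tree + Markov model.

    All probabilities, utilities, shares and fractions live in [0, 1]; costs
    are non-negative USD. ``soc_utilization`` must sum to one.
    """

    model_config = {"validate_assignment": True}

    # Decision tree
    p_high: float = Field(0.1872, ge=0.0, le=1.0,
                          description="fraction of tested patients predicted high risk")
    soc_utilization: dict[str, float] = Field(
        default_factory=lambda: {SBRT: 0.3830, CFRT: 0.1235, PROSTATECTOMY: 0.4935})
    surgery_diversion: float = Field(0.80, ge=0.0, le=1.0,
                                     description="reduction of the prostatectomy share among tested low-risk patients")
    radiation_adherence: float = Field(1.0, ge=0.0, le=1.0,
                                       description="fraction of tested radiation patients following the recommended modality")
    # Baseline prostatectomy utilization among tested patients. ``None`` means
    # "track the SOC prostatectomy share" (the default coupling); sensitivity
    # analyses that vary one printed utilization row at a time pin this to the
    # base value so the arms can move independently.
    tested_prostatectomy_share: Optional[float] = Field(None, ge=0.0, le=1.0)

    # Markov transition inputs
    tox_p1: dict[str, float] = Field(default_factory=lambda: {
        "T1": 0.2778, "T2": 0.0396, "T3": 0.1189,
        "T4": 0.0124, "T5": 0.0396, "T6": 0.1189,
        "T7": 0.0499, "T8": 0.0396, "T9": 0.1189,
    })
    taper: float = Field(0.7013, gt=0.0, le=1.0,
                         description="annual multiplicative toxicity-development taper for cycles >= 5")

    # Utilities and discounting
    u_notox: float = Field(0.90, ge=0.0, le=1.0)
    u_tox: float = Field(0.70, ge=0.0, le=1.0)
    d_cost: float = Field(0.03, ge=0.0)
    d_util: float = Field(0.03, ge=0.0)
    discounting_enabled: bool = True

    # Costs (2024 USD)
    c_treat: dict[str, float] = Field(default_factory=lambda: {
        SBRT: 20670.28, CFRT: 42642.68, PROSTATECTOMY: 97782.37})
    c_test: float = Field(4000.00, ge=0.0)
    c_notox: float = Field(2914.90, ge=0.0, description="annual cost of care without toxicity")
    c_tox: float = Field(5774.58, ge=0.0, description="annual cost of care with toxicity")

    # Simulation settings
    cohort_size: int = Field(10_000, ge=1)
    start_age: int = Field(67, ge=0)
    cycle_length: float = Field(1.0, gt=0.0)

    # Analysis settings
    wtp_default: float = Field(100_000.0, ge=0.0)
    psa_iterations: int = Field(10_000, ge=1)
    psa_default_se_frac: float = Field(0.10, gt=0.0, le=1.0)
    dsa_delta: float = Field(0.20, gt=0.0, lt=1.0)

    @field_validator("soc_utilization")
    @classmethod
    def _check_shares(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(MODALITIES):
            raise ValueError(f"soc_utilization must cover exactly {MODALITIES}, got {sorted(v)}")
        for name, share in v.items():
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"soc_utilization[{name}]={share} outside [0, 1]")
        total = sum(v.values())
        if abs(total - 1.0) > _SHARE_TOL:
            raise ValueError(f"soc_utilization shares sum to {total!r}, not 1")
        return v

    @field_validator("tox_p1")
    @classmethod
    def _check_tox(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(TRACKS):
            raise ValueError(f"tox_p1 must cover tracks T1-T9, got {sorted(v)}")
        for track, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"tox_p1[{track}]={p} outside [0, 1]")
        return v

    @field_validator("c_treat")
    @classmethod
    def _check_costs(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(MODALITIES):
            raise ValueError(f"c_treat must cover exactly {MODALITIES}, got {sorted(v)}")
        for name, cost in v.items():
            if cost < 0:
                raise ValueError(f"c_treat[{name}]={cost} is negative")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "ModelParameters":
        if self.u_tox > self.u_notox:
            # legitimate in probabilistic draws, so debug-level only
            logger.debug("u_tox (%s) exceeds u_notox (%s): toxicity improves quality of life",
                         self.u_tox, self.u_notox)
        return self

    def prostatectomy_share_tested(self) -> float:
        """Baseline prostatectomy utilization among tested patients."""
        if self.tested_prostatectomy_share is not None:
            return self.tested_prostatectomy_share
        return self.soc_utilization[PROSTATECTOMY]

    def param_hash(self) -> str:
        """Stable hash of the resolved parameter values (for run manifests)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_parameters() -> ModelParameters:
    """Return the bundled base-case parameter set."""
    return ModelParameters()


def load_config(path: str | Path) -> ModelParameters:
    """Load a JSON parameter file; unspecified fields fall back to defaults.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` (via
    pydantic) naming the offending field for schema or invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a JSON object, got {type(raw).__name__}")
    unknown = set(raw) - set(ModelParameters.model_fields)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    params = ModelParameters(**raw)
    logger.info("loaded parameters from %s (hash %s)", path, params.param_hash())
    return params


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write the full parameter set as JSON; round-trips losslessly via load_config."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(params.model_dump(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("saved parameters to %s (hash %s)", path, params.param_hash())


# ---------------------------------------------------------------------------
# Printed per-track outcomes table (worked-example fixture)
# ---------------------------------------------------------------------------

_FIXTURE_COLUMNS = ["track", "weight_pct", "cost_t0", "cost_y1", "cost_y2",
                    "cost_y3", "cost_y4", "cost_y5", "lifetime_cost", "lifetime_qalys"]

TRACK_ARM = {t: (PROSTOX if t in PROSTOX_TRACKS else SOC) for t in TRACKS}


class PrintedTrackTable:
    """The published per-patient outcomes table, one row per track T1-T9.

    Columns: track weight (%), one-off treatment cost at model entry (USD),
    annual clinical costs for years 1-5 (USD; these cells are already scaled
    by the track weight in the source table — see the aggregation notes in
    :mod:`prostox_cea.economics`), lifetime cost and lifetime QALYs.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(_FIXTURE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"printed table missing columns: {sorted(missing)}")
        frame = frame[_FIXTURE_COLUMNS].copy()
        if list(frame["track"]) != list(TRACKS):
            raise ValueError(f"printed table must have exactly the nine rows T1-T9 in order, "
                             f"got {list(frame['track'])}")
        numeric = frame.drop(columns="track")
        if (numeric.to_numpy() < 0).any():
            raise ValueError("printed table contains negative entries")
        for arm, tracks in ((PROSTOX, PROSTOX_TRACKS), (SOC, SOC_TRACKS)):
            total = frame.set_index("track").loc[list(tracks), "weight_pct"].sum()
            if abs(total - 100.0) > 0.1:
                raise ValueError(f"{arm} track weights sum to {total}, not 100%")
        self.frame = frame.set_index("track")

    def weights(self, arm: str) -> pd.Series:
        tracks = PROSTOX_TRACKS if arm == PROSTOX else SOC_TRACKS
        return self.frame.loc[list(tracks), "weight_pct"] / 100.0

    def arm_rows(self, arm: str) -> pd.DataFrame:
        tracks = PROSTOX_TRACKS if arm == PROSTOX else SOC_TRACKS
        return self.frame.loc[list(tracks)]


def load_printed_table(path: str | Path | None = None) -> PrintedTrackTable:
    """Load the per-track outcomes table; default is the bundled fixture."""
    if path is None:
        ref = resources.files("prostox_cea.data") / "track_table.csv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p)
        logger.info("loaded bundled printed track table")
    else:
        frame = pd.read_csv(path)
        logger.info("loaded printed track table from %s", path)
    return PrintedTrackTable(frame)
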