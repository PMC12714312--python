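"""Decision tree: allocate each arm's population across the nine treatment tracks.

Tested patients are stratified by predicted toxicity risk. With full adherence,
high-risk patients avoid SBRT (radiation goes to CFRT) and low-risk patients
avoid CFRT (radiation goes to SBRT); in addition, a fraction
``surgery_diversion`` of the low-risk surgical candidates choose SBRT over
prostatectomy. The standard-of-care arm follows the literature utilization mix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import (
    ARMS, CFRT, MODALITIES, PROSTATECTOMY, PROSTOX, PROSTOX_TRACKS, SBRT, SOC,
    SOC_TRACKS, TRACK_MODALITY, TRACKS, ModelParameters,
)

HIGH = "high"
LOW = "low"

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class TrackWeights:
    """Per-arm mapping of tracks T1-T9 to population fractions.

    The tested arm puts zero weight on T7-T9 and the standard-of-care arm
    zero on T1-T6; within-arm fractions sum to one.
    """

    arm: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if set(self.weights) != set(TRACKS):
            raise ValueError("weights must cover tracks T1-T9")
        foreign = SOC_TRACKS if self.arm == PROSTOX else PROSTOX_TRACKS
        for t in foreign:
            if self.weights[t] != 0.0:
                raise ValueError(f"{self.arm} arm has nonzero weight on {t}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.arm} weights sum to {total}, not 1")

    def __getitem__(self, track: str) -> float:
        return self.weights[track]

    def nonzero(self) -> dict[str, float]:
        return {t: w for t, w in self.weights.items() if w > _WEIGHT_TOL}


def derive_stratum_utilization(params: ModelParameters, stratum: str) -> dict[str, float]:
    """Treatment-utilization shares within a tested risk stratum.

    High risk: the prostatectomy share stays at its baseline; the radiation
    remainder goes to CFRT, except that a non-adherent fraction stays on SBRT.
    Low risk: the prostatectomy share shrinks by ``surgery_diversion`` (the
    diverted patients take SBRT); the radiation remainder goes to SBRT except
    for a non-adherent fraction on CFRT.
    """
    if stratum not in (HIGH, LOW):
        raise ValueError(f"unknown stratum {stratum!r}; expected '{HIGH}' or '{LOW}'")
    p_surg = params.prostatectomy_share_tested()
    adh = params.radiation_adherence
    if stratum == HIGH:
        radiation = 1.0 - p_surg
        shares = {SBRT: radiation * (1.0 - adh), CFRT: radiation * adh,
                  PROSTATECTOMY: p_surg}
    else:
        p_surg_low = p_surg * (1.0 - params.surgery_diversion)
        radiation = 1.0 - p_surg_low
        shares = {SBRT: radiation * adh, CFRT: radiation * (1.0 - adh),
                  PROSTATECTOMY: p_surg_low}
    assert abs(sum(shares.values()) - 1.0) < 1e-12
    return shares


def compute_track_weights(params: ModelParameters, arm: str) -> TrackWeights:
    """Population fraction entering each track for one arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    weights = dict.fromkeys(TRACKS, 0.0)
    if arm == PROSTOX:
        high = derive_stratum_utilization(params, HIGH)
        low = derive_stratum_utilization(params, LOW)
        weights["T1"] = params.p_high * high[SBRT]
        weights["T2"] = params.p_high * high[CFRT]
        weights["T3"] = params.p_high * high[PROSTATECTOMY]
        weights["T4"] = (1.0 - params.p_high) * low[SBRT]
        weights["T5"] = (1.0 - params.p_high) * low[CFRT]
        weights["T6"] = (1.0 - params.p_high) * low[PROSTATECTOMY]
    else:
        weights["T7"] = params.soc_utilization[SBRT]
        weights["T8"] = params.soc_utilization[CFRT]
        weights["T9"] = params.soc_utilization[PROSTATECTOMY]
    return TrackWeights(arm=arm, weights=weights)


def modality_shares(weights: TrackWeights) -> dict[str, float]:
    """Sum track weights by treatment modality."""
    shares = dict.fromkeys(MODALITIES, 0.0)
    for track, w in weights.weights.items():
        shares[TRACK_MODALITY[track]] += w
    return shares
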