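#!/usr/bin/env python
"""Decision-tree stage: where does each arm's population go?

Computes the nine track weights for the risk-guided and standard-of-care
arms and the per-modality shares, and writes them to results/track_weights.csv.
"""

from pathlib import Path

import pandas as pd

from prostox_cea import compute_track_weights, default_parameters, modality_shares
from prostox_cea.params import ARMS, TRACKS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_parameters()
    rows = []
    for arm in ARMS:
        weights = compute_track_weights(params, arm)
        for track in TRACKS:
            rows.append({"arm": arm, "track": track,
                         "weight_pct": round(100 * weights[track], 2)})
        shares = {m: round(100 * s, 2) for m, s in
                  modality_shares(weights).items()}
        print(f"{arm}: modality shares {shares}")
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "track_weights.csv", index=False)

    tested = frame[frame["arm"] == "PROSTOX"].set_index("track")["weight_pct"]
    print(f"\nRisk-guided arm: {tested['T2']}% high-risk CFRT (T2), "
          f"{tested['T3']}% high-risk surgery (T3), {tested['T4']}% low-risk SBRT (T4), "
          f"{tested['T6']}% low-risk surgery (T6); T1/T5 empty under full adherence.")
    print(f"wrote {OUT / 'track_weights.csv'}")


if __name__ == "__main__":
    main()
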