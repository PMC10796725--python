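"""Simulated GI trials: noise-free exactness and replicate-level bias.

First shows that a noise-free 10-subject trial returns every programmed GI
exactly; then runs 200 replicate trials at programmed GI 60 under the
study's measurement-noise conditions and reports the bias and spread of
the study-level GI estimate.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from endograin import glycemia as G
from endograin.synthetic_data import CurveParams, generate_glycemic_curves

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 10_000) -> None:
    (ROOT / "results").mkdir(exist_ok=True)

    programmed = {"low_food": 49.15, "medium_food": 64.17, "high_food": 92.31}
    df, _ = generate_glycemic_curves(programmed, CurveParams(noise_sd=0.0), seed=seed)
    exact = G.gi_table(df)
    print("noise-free trial (programmed GI recovered exactly):")
    print(exact.to_string(index=False))

    means, sds = [], []
    for rep in range(200):
        df, _ = generate_glycemic_curves({"rice": 60.0}, seed=seed + rep)
        out = G.gi_table(df)
        means.append(out["gi_mean"].iloc[0])
        sds.append(out["gi_sd"].iloc[0])
    summary = pd.DataFrame({
        "programmed_gi": [60.0],
        "mean_of_study_means": [float(np.mean(means))],
        "bias": [float(np.mean(means)) - 60.0],
        "sd_of_study_means": [float(np.std(means))],
        "mean_per_subject_sd": [float(np.mean(sds))],
        "n_replicates": [200],
    }).round(3)
    summary.to_csv(ROOT / "results" / "gi_simulation.csv", index=False)
    print("\n200-replicate 10-subject trials at programmed GI 60:")
    print(summary.to_string(index=False))
    print(f"\nfinding: study-level bias {summary.bias[0]:+.2f} GI units; "
          f"per-subject spread ~{summary.mean_per_subject_sd[0]:.1f} GI units, "
          "comparable to the reported inter-subject variability")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 10_000)
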