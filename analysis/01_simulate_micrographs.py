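"""Generate a batch of ground-truthed synthetic endosperm fields.

Renders fields spanning the observed porosity range (0.4-6.7 %), writes
the images and ground-truth masks under scratch/ (binary artefacts) and a
per-field ground-truth summary under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from endograin.synthetic_data import MicrographParams, generate_micrograph

ROOT = Path(__file__).resolve().parents[1]
OUT_IMG = ROOT / "scratch" / "sim_micrographs"
OUT_TAB = ROOT / "results"


def main(seed: int = 0) -> None:
    OUT_IMG.mkdir(parents=True, exist_ok=True)
    OUT_TAB.mkdir(exist_ok=True)
    rows = []
    targets = np.round(np.linspace(0.4, 6.7, 12), 2)
    for i, target in enumerate(targets):
        params = MicrographParams(target_porosity_pct=float(target))
        micro, truth = generate_micrograph(params, seed=seed + i)
        stem = f"field_{i:02d}"
        tifffile.imwrite(OUT_IMG / f"{stem}.tif", (micro.pixels * 65535).astype("uint16"))
        tifffile.imwrite(OUT_IMG / f"{stem}_truth.tif", truth.granule_labels.astype("uint16"))
        rows.append({
            "field": stem,
            "programmed_porosity_pct": truth.programmed_porosity_pct,
            "achieved_porosity_pct": round(truth.achieved_porosity_pct, 3),
            "shadow_area_pct": round(100 * truth.shadow_mask.mean(), 3),
            "n_granules": int((truth.granule_areas_um2 > 0).sum()),
            "mean_granule_area_um2": round(
                truth.granule_areas_um2[truth.granule_areas_um2 > 0].mean(), 3
            ),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT_TAB / "simulated_fields.csv", index=False)
    print(f"wrote {len(rows)} fields to {OUT_IMG} (images) and "
          f"{OUT_TAB/'simulated_fields.csv'} (ground truth)")
    print(table.to_string(index=False))
    dev = (table.achieved_porosity_pct - table.programmed_porosity_pct).abs().max()
    print(f"\nfinding: programmed porosity is realised to within {dev:.3f} points")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
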