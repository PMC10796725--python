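"""Reading micrographs + metadata sidecars and writing result tables.

Images are 8/16-bit grayscale TIFF or PNG; calibration comes from a
metadata CSV (one row per image: variety_id, grain_id, field_id,
magnification, pixel_size_um, region_tag, chalky_fraction_pct) — pixel
size is never inferred from magnification.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .morphometry import FieldMorphometry, GranuleShape, Micrograph, SegmentationLabels

__all__ = [
    "read_micrograph",
    "iter_micrographs",
    "write_label_maps",
    "granules_to_frame",
    "field_summaries_to_frame",
    "variety_to_frame",
]

META_COLUMNS = [
    "filename", "variety_id", "grain_id", "field_id",
    "magnification", "pixel_size_um", "region_tag", "chalky_fraction_pct",
]


def read_micrograph(path: str | Path, meta_row: pd.Series) -> Micrograph:
    """One calibrated micrograph from an image file plus its metadata row."""
    px = np.asarray(iio.imread(path)).astype(float)
    if px.ndim == 3:  # collapse an (identical-channel) RGB export
        px = px.mean(axis=-1)
    return Micrograph(
        pixels=px,
        pixel_size=float(meta_row["pixel_size_um"]),
        magnification=float(meta_row.get("magnification", np.nan)),
        variety_id=str(meta_row["variety_id"]),
        grain_id=str(meta_row["grain_id"]),
        field_id=str(meta_row["field_id"]),
        region_tag=str(meta_row.get("region_tag", "unknown")),
    )


def iter_micrographs(image_dir: str | Path, meta_csv: str | Path) -> Iterator[tuple[Micrograph, pd.Series]]:
    """Yield (micrograph, metadata row) for every file listed in the sidecar."""
    image_dir = Path(image_dir)
    meta = pd.read_csv(meta_csv)
    missing = set(META_COLUMNS[:2]) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata CSV is missing columns: {sorted(missing)}")
    for _, row in meta.iterrows():
        yield read_micrograph(image_dir / row["filename"], row), row


def write_label_maps(labels: SegmentationLabels, out_dir: str | Path, stem: str) -> None:
    """Write the instance map and class masks as 16-bit TIFFs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}_granules.tif", labels.granule_labels.astype(np.uint16))
    classes = np.zeros(labels.granule_labels.shape, dtype=np.uint16)
    classes[labels.pore_mask] = 1
    classes[labels.shadow_mask] = 2
    classes[labels.background_mask] = 3
    tifffile.imwrite(out / f"{stem}_classes.tif", classes)


def granules_to_frame(shapes: list[GranuleShape]) -> pd.DataFrame:
    """Per-granule table with the report column names."""
    return pd.DataFrame(
        {
            "area_um2": [s.area_um2 for s in shapes],
            "perimeter_um": [s.perimeter_um for s in shapes],
            "eccentricity": [s.eccentricity for s in shapes],
            "circularity": [s.circularity for s in shapes],
            "equivalent_diameter_um": [s.equivalent_diameter_um for s in shapes],
            "touches_border": [s.touches_border for s in shapes],
        }
    )


def field_summaries_to_frame(rows: list[tuple[str, str, str, FieldMorphometry]]) -> pd.DataFrame:
    """Per-field table from (variety, grain, field, summary) tuples."""
    recs = []
    for variety, grain, fid, s in rows:
        recs.append(
            {"variety_id": variety, "grain_id": grain, "field_id": fid,
             "porosity_pct": s.porosity_pct, "n_granules": s.n_granules,
             "mean_area_um2": s.mean_area_um2, "sd_area_um2": s.sd_area_um2,
             "mean_eccentricity": s.mean_eccentricity,
             "mean_circularity": s.mean_circularity,
             "shape_undefined": s.shape_undefined, "compact": s.compact}
        )
    return pd.DataFrame(recs)


def variety_to_frame(rows) -> pd.DataFrame:
    """Per-variety table mirroring the printed report semantics."""
    return pd.DataFrame(
        {
            "variety": [v.variety_id for v in rows],
            "area_um2": [v.mean_area_um2 for v in rows],
            "area_sd": [v.sd_area_um2 for v in rows],
            "eccentricity": [v.mean_eccentricity for v in rows],
            "circularity": [v.mean_circularity for v in rows],
            "diameter_um": [v.estimated_diameter_um for v in rows],
            "porosity_pct": [v.mean_porosity_pct for v in rows],
            "porosity_sd": [v.sd_porosity_pct for v in rows],
            "chalky_fraction_pct": [v.chalky_fraction_pct for v in rows],
            "n_grains": [v.n_grains for v in rows],
            "n_fields": [v.n_fields for v in rows],
        }
    ).set_index("variety")
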