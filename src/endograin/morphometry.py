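"""Starch-granule morphometry for FESEM endosperm micrographs.

A longitudinal grain section imaged at 5000X shows compound starch granules
(bright, polyhedral, ~2-12 um across) separated by gaps.  A gap is either a
true pore (empty inter-granular space) or a shadow cast by the capture
perspective.  This module segments a calibrated micrograph into granule
instances, pores and shadows, measures per-granule shape descriptors, and
aggregates field-level summaries into per-variety values weighted by the
chalky fraction of the endosperm.

Conventions
-----------
area            pixel count x pixel_size**2                     [um^2]
perimeter       Crofton-style region perimeter x pixel_size     [um]
eccentricity    of the ellipse with matching second central moments
                (0 = circle, -> 1 elongated)
circularity     4*pi*A / P**2, clipped to 1 (1 = circle)
equiv. diameter 2*sqrt(area/pi), the diameter of the equal-area disc
porosity        100 * pore px / (pore + shadow + granule px)    [%]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import spearmanr
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "Micrograph",
    "SegmentationLabels",
    "SegmentationParams",
    "VoidParams",
    "GranuleShape",
    "FieldMorphometry",
    "VarietyMorphometry",
    "NoStructureError",
    "segment_micrograph",
    "classify_voids",
    "measure_granules",
    "equivalent_diameter",
    "field_summary",
    "aggregate_variety",
    "round_half_up",
]


class NoStructureError(ValueError):
    """The image has no intensity separation between granules and voids."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as in the printed report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

RegionTag = Literal["chalky", "crystalline", "unknown"]


@dataclass
class Micrograph:
    """A calibrated grayscale micrograph of a grain section.

    Parameters
    ----------
    pixels
        2-D float intensity grid (any monotone scale; 8/16-bit inputs are
        accepted as-is).
    pixel_size
        Physical size of one pixel edge in micrometres. Required: it is never
        inferred from the nominal magnification.
    region_tag
        Whether the field lies in the chalky or crystalline (vitreous) part
        of the endosperm, used for chalky-weighted variety aggregation.
    """

    pixels: np.ndarray
    pixel_size: float
    magnification: float | None = None
    variety_id: str = ""
    grain_id: str = ""
    field_id: str = ""
    region_tag: RegionTag = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if not (self.pixel_size is not None and self.pixel_size > 0):
            raise ValueError("pixel_size (um/px) must be positive; calibration is required")
        if self.region_tag not in ("chalky", "crystalline", "unknown"):
            raise ValueError(f"unknown region_tag {self.region_tag!r}")


@dataclass
class SegmentationLabels:
    """Mutually exclusive partition of a micrograph.

    ``granule_labels > 0`` marks granule instances; ``pore_mask``,
    ``shadow_mask`` and ``background_mask`` partition the remaining pixels.
    """

    granule_labels: np.ndarray
    pore_mask: np.ndarray
    shadow_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        g = self.granule_labels > 0
        masks = np.stack([g, self.pore_mask, self.shadow_mask, self.background_mask])
        counts = masks.sum(axis=0)
        if not np.all(counts == 1):
            raise ValueError("granule/pore/shadow/background must partition the image")

    @property
    def void_mask(self) -> np.ndarray:
        return self.pore_mask | self.shadow_mask

    def porosity(self) -> float:
        """Porosity in % of the analysed (non-background) area."""
        analysed = (~self.background_mask).sum()
        if analysed == 0:
            return float("nan")
        return 100.0 * self.pore_mask.sum() / analysed


@dataclass
class SegmentationParams:
    """Settings for :func:`segment_micrograph`.

    threshold
        ``"otsu"`` or a percentile in (0, 100) of the smoothed intensities.
    min_area_um2
        Regions (granule or void) smaller than this are merged into the
        surrounding class.
    split_touching
        Split connected granule regions into compound-granule wedges with a
        marker-based watershed on the distance transform.
    min_peak_distance_um
        Minimum distance between watershed markers; roughly the smallest
        granule diameter worth splitting out.
    """

    threshold: float | str = "otsu"
    smooth_sigma_px: float = 0.7
    min_area_um2: float = 1.0
    # voids only need despeckling: inter-granular gaps are far smaller than
    # the smallest granule worth keeping
    min_void_area_um2: float = 0.02
    split_touching: bool = True
    min_peak_distance_um: float = 2.0
    # granule/void class means must differ by this many granule-class sds,
    # else the field is treated as uniform granule matter (no voids); a
    # unimodal noise field split at its Otsu threshold gives ~2.7
    min_contrast_sds: float = 3.5


@dataclass
class VoidParams:
    """Settings for the pore/shadow decision rule (see :func:`classify_voids`)."""

    pore_ceiling: float | None = None  # None -> midpoint of pore and granule modes
    ramp_corr_threshold: float = 0.6
    min_ramp_pixels: int = 12
    histogram_bins: int = 64
    # hysteresis: sub-ceiling void pixels above this fraction of the
    # pore-mode -> ceiling span join an adjacent supra-ceiling shadow
    hysteresis_floor_frac: float = 0.5


@dataclass
class GranuleShape:
    """Shape descriptors of one granule instance (physical units)."""

    label: int
    area_um2: float
    perimeter_um: float
    eccentricity: float
    circularity: float
    equivalent_diameter_um: float
    centroid_rc: tuple[float, float]
    touches_border: bool


@dataclass
class FieldMorphometry:
    """Per-image summary: porosity plus shape statistics over interior granules."""

    porosity_pct: float
    n_granules: int
    mean_area_um2: float
    sd_area_um2: float
    mean_perimeter_um: float
    sd_perimeter_um: float
    mean_eccentricity: float
    sd_eccentricity: float
    mean_circularity: float
    sd_circularity: float
    shape_undefined: bool = False
    compact: bool = False


@dataclass
class VarietyMorphometry:
    """Chalky-fraction weighted per-variety aggregate (a report-table row)."""

    variety_id: str
    mean_area_um2: float
    sd_area_um2: float
    mean_eccentricity: float
    mean_circularity: float
    estimated_diameter_um: float
    mean_porosity_pct: float
    sd_porosity_pct: float
    chalky_fraction_pct: float
    n_grains: int
    n_fields: int


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _min_area_px(min_area_um2: float, pixel_size: float) -> int:
    return max(1, int(round(min_area_um2 / pixel_size**2)))


def segment_micrograph(
    image: Micrograph, params: SegmentationParams | None = None
) -> SegmentationLabels:
    """Partition a micrograph into granule instances and provisional voids.

    The smoothed intensities are thresholded (Otsu by default) into bright
    granule matter and dark voids; small regions on either side are merged
    into their surroundings; connected granule matter is optionally split
    into compound-granule wedges by a watershed on the distance transform.
    All void pixels are returned provisionally as pores —
    :func:`classify_voids` resolves pores vs shadows.

    Raises
    ------
    NoStructureError
        If the image is constant or the threshold separates nothing.
    """
    params = params or SegmentationParams()
    px = image.pixels
    if np.ptp(px) == 0:
        raise NoStructureError("no structure detected: constant-intensity image")

    smoothed = gaussian(px, sigma=params.smooth_sigma_px, preserve_range=True)
    if params.threshold == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = np.percentile(smoothed, float(params.threshold))
    granule_mask = smoothed >= thr
    if granule_mask.any() and (~granule_mask).any():
        g, v = smoothed[granule_mask], smoothed[~granule_mask]
        g_sd = float(g.std())
        if g_sd > 0 and (g.mean() - v.mean()) < params.min_contrast_sds * g_sd:
            # unimodal field (e.g. uniform granule matter + noise): no voids
            granule_mask = np.ones_like(granule_mask)
    if not granule_mask.any():
        raise NoStructureError("no structure detected: threshold found no granule matter")

    granule_mask = _merge_small_regions(
        granule_mask,
        min_granule_px=_min_area_px(params.min_area_um2, image.pixel_size),
        min_void_px=_min_area_px(params.min_void_area_um2, image.pixel_size),
    )

    if params.split_touching:
        labels = _watershed_split(
            granule_mask,
            min_peak_distance_px=max(
                1, int(round(params.min_peak_distance_um / image.pixel_size))
            ),
        )
    else:
        labels = cc_label(granule_mask, connectivity=1)

    void = ~granule_mask
    return SegmentationLabels(
        granule_labels=labels,
        pore_mask=void,
        shadow_mask=np.zeros_like(void),
        background_mask=np.zeros_like(void),
    )


def _merge_small_regions(
    granule_mask: np.ndarray, min_granule_px: int, min_void_px: int
) -> np.ndarray:
    """Absorb sub-minimum granule islands and void specks into their surroundings."""
    out = granule_mask.copy()
    lab = cc_label(out, connectivity=1)
    for r in regionprops(lab):
        if r.area < min_granule_px:
            out[lab == r.label] = False
    lab = cc_label(~out, connectivity=1)
    for r in regionprops(lab):
        if r.area < min_void_px:
            out[lab == r.label] = True
    return out


def _watershed_split(granule_mask: np.ndarray, min_peak_distance_px: int) -> np.ndarray:
    from skimage.feature import peak_local_max

    dist = ndi.distance_transform_edt(granule_mask)
    coords = peak_local_max(
        dist,
        min_distance=min_peak_distance_px,
        labels=granule_mask,
        exclude_border=False,
    )
    markers = np.zeros(granule_mask.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return cc_label(granule_mask, connectivity=1)
    labels = watershed(-dist, markers, mask=granule_mask)
    # watershed can leave masked pixels unreached (diagonal-only necks);
    # assign them to the nearest labelled pixel to keep the partition exact
    orphan = granule_mask & (labels == 0)
    if orphan.any():
        idx = ndi.distance_transform_edt(
            labels == 0, return_distances=False, return_indices=True
        )
        labels = np.where(orphan, labels[tuple(idx)], labels)
    return labels


# ---------------------------------------------------------------------------
# pore vs shadow
# ---------------------------------------------------------------------------


def _intensity_mode(values: np.ndarray, lo: float, hi: float, bins: int) -> float:
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def classify_voids(
    image: Micrograph,
    labels: SegmentationLabels,
    params: VoidParams | None = None,
) -> SegmentationLabels:
    """Assign every provisional void pixel to exactly one of {pore, shadow}.

    A void pixel or region is a *shadow* when either

    a. its intensity exceeds the pore ceiling (default: midpoint between
       the pore mode and the granule mode of the intensity histogram) —
       perspective shadows are only partially occluded, so they image
       brighter than true empty space; or
    b. its (sub-ceiling) connected region exhibits a monotone intensity
       ramp away from the adjacent granule edge: Spearman rank correlation
       of the region's intensities with the distance to the nearest
       granule pixel exceeds ``ramp_corr_threshold`` (a cast shadow is
       darkest against the occluding edge and fades with distance).

    Rule (a) is applied per pixel and rule (b) per connected sub-ceiling
    region: the inter-granular gap network of a packed section is a single
    connected component, so a component-level vote would flip pores and
    shadows wholesale.  The decision is deterministic given the
    parameters; with no void pixels both masks come back empty.
    """
    params = params or VoidParams()
    void = labels.void_mask
    granule = labels.granule_labels > 0
    pore_mask = np.zeros_like(void)
    shadow_mask = np.zeros_like(void)
    if not void.any():
        return SegmentationLabels(
            labels.granule_labels, pore_mask, shadow_mask, labels.background_mask
        )

    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if params.pore_ceiling is not None:
        ceiling = params.pore_ceiling
    elif hi > lo and granule.any():
        pore_mode = _intensity_mode(px[void], lo, hi, params.histogram_bins)
        granule_mode = _intensity_mode(px[granule], lo, hi, params.histogram_bins)
        ceiling = 0.5 * (pore_mode + granule_mode)
    else:
        ceiling = np.inf  # nothing to compare against: treat all voids as pores

    bright = void & (px > ceiling)
    if bright.any() and np.isfinite(ceiling):
        # hysteresis: the dark tail of a shadow ramp sits below the ceiling
        # but above typical pore grey and touches the supra-ceiling part
        pore_mode = _intensity_mode(px[void], lo, hi, params.histogram_bins)
        floor = pore_mode + params.hysteresis_floor_frac * (ceiling - pore_mode)
        grown = cc_label(void & (px > floor), connectivity=1)
        keep = np.unique(grown[bright])
        bright = bright | (np.isin(grown, keep[keep > 0]) & void)
    shadow_mask |= bright

    dist_to_granule = ndi.distance_transform_edt(~granule)
    comp = cc_label(void & ~bright, connectivity=1)
    for r in regionprops(comp):
        idx = comp == r.label
        vals = px[idx]
        is_shadow = False
        graded = float(np.median(np.abs(vals - np.median(vals)))) > 0
        if graded and vals.size >= params.min_ramp_pixels:
            # a ramp needs graded intensities throughout; a flat component
            # with a few boundary outliers (median absolute deviation 0)
            # is never a ramp
            d = dist_to_granule[idx]
            if np.ptp(d) > 0:
                rho = spearmanr(vals, d).statistic
                is_shadow = bool(np.isfinite(rho) and rho > params.ramp_corr_threshold)
        if is_shadow:
            shadow_mask[idx] = True
        else:
            pore_mask[idx] = True

    return SegmentationLabels(
        labels.granule_labels, pore_mask, shadow_mask, labels.background_mask
    )


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def equivalent_diameter(area_um2: float) -> float:
    """Diameter (um) of the circle with the given area, to 2 decimals.

    The report tables estimate granule diameter from mean area treating
    granules as approximately round: d = 2*sqrt(A/pi).
    """
    if not (area_um2 > 0):
        raise ValueError(f"area must be positive, got {area_um2}")
    return round_half_up(2.0 * math.sqrt(area_um2 / math.pi), 2)


def measure_granules(
    labels: SegmentationLabels, pixel_size: float
) -> list[GranuleShape]:
    """Per-granule shape descriptors in physical units.

    Granules touching the image border are flagged (their shapes are
    truncated) but still measured; zero granules yields an empty list.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    nrow, ncol = labels.granule_labels.shape
    out: list[GranuleShape] = []
    for r in regionprops(labels.granule_labels):
        minr, minc, maxr, maxc = r.bbox
        touches = minr == 0 or minc == 0 or maxr == nrow or maxc == ncol
        area = r.area * pixel_size**2
        perim = r.perimeter * pixel_size
        circ = 4.0 * math.pi * area / perim**2 if perim > 0 else 1.0
        out.append(
            GranuleShape(
                label=r.label,
                area_um2=area,
                perimeter_um=perim,
                eccentricity=float(r.eccentricity),
                circularity=min(circ, 1.0),
                equivalent_diameter_um=2.0 * math.sqrt(area / math.pi),
                centroid_rc=tuple(r.centroid),
                touches_border=touches,
            )
        )
    return out


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        return float("nan"), float("nan")
    return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0


def field_summary(
    shapes: Sequence[GranuleShape],
    labels: SegmentationLabels,
    compact_coverage: float = 0.95,
) -> FieldMorphometry:
    """Summarise one field: porosity plus shape statistics.

    Porosity uses the final pore mask over the analysed (non-background)
    area; shadows count in the denominator but not the numerator.  Shape
    statistics exclude border-touching granules.  A field whose granule
    matter collapses into a single region covering more than
    ``compact_coverage`` of the non-void area is flagged compact — the
    granules are indistinguishable (as in very compact or waxy endosperm)
    and shape features are reported as missing; porosity is still valid.
    """
    porosity = labels.porosity()
    n_instances = int(labels.granule_labels.max())
    granule_px = int((labels.granule_labels > 0).sum())
    analysed_px = int((~labels.background_mask).sum())
    nonvoid_px = analysed_px - int(labels.void_mask.sum())
    # compact endosperm: granule matter is one unsplittable region filling
    # essentially the whole field (an isolated granule in a sparse field is
    # not compact, however dominant within the non-void area)
    compact = (
        n_instances == 1
        and nonvoid_px > 0
        and granule_px / nonvoid_px > compact_coverage
        and analysed_px > 0
        and granule_px / analysed_px > 0.9
    )

    interior = [s for s in shapes if not s.touches_border]
    undefined = compact or len(interior) == 0
    if undefined:
        nan = float("nan")
        return FieldMorphometry(
            porosity_pct=porosity, n_granules=len(shapes),
            mean_area_um2=nan, sd_area_um2=nan,
            mean_perimeter_um=nan, sd_perimeter_um=nan,
            mean_eccentricity=nan, sd_eccentricity=nan,
            mean_circularity=nan, sd_circularity=nan,
            shape_undefined=True, compact=compact,
        )

    m_area, s_area = _mean_sd([s.area_um2 for s in interior])
    m_per, s_per = _mean_sd([s.perimeter_um for s in interior])
    m_ecc, s_ecc = _mean_sd([s.eccentricity for s in interior])
    m_circ, s_circ = _mean_sd([s.circularity for s in interior])
    return FieldMorphometry(
        porosity_pct=porosity, n_granules=len(shapes),
        mean_area_um2=m_area, sd_area_um2=s_area,
        mean_perimeter_um=m_per, sd_perimeter_um=s_per,
        mean_eccentricity=m_ecc, sd_eccentricity=s_ecc,
        mean_circularity=m_circ, sd_circularity=s_circ,
    )


# ---------------------------------------------------------------------------
# variety aggregation
# ---------------------------------------------------------------------------


@dataclass
class FieldRecord:
    """One field summary with its provenance (grain and endosperm region)."""

    grain_id: str
    region_tag: RegionTag
    summary: FieldMorphometry


def _grain_then_variety_mean(
    records: Sequence[FieldRecord], attr: str
) -> tuple[float, float, int, int]:
    """Mean of per-grain means (fields -> grain -> variety) and across-grain sd."""
    by_grain: dict[str, list[float]] = {}
    for rec in records:
        v = getattr(rec.summary, attr)
        if np.isfinite(v):
            by_grain.setdefault(rec.grain_id, []).append(v)
    grain_means = [float(np.mean(v)) for v in by_grain.values()]
    n_fields = sum(len(v) for v in by_grain.values())
    if not grain_means:
        return float("nan"), float("nan"), 0, 0
    mean = float(np.mean(grain_means))
    sd = float(np.std(grain_means, ddof=1)) if len(grain_means) > 1 else 0.0
    return mean, sd, len(by_grain), n_fields


def _weighted(chalky: float, crystalline: float, w_pct: float) -> float:
    w = w_pct / 100.0
    if w == 0.0 or not np.isfinite(chalky):
        return crystalline
    if w == 1.0 or not np.isfinite(crystalline):
        return chalky
    return w * chalky + (1.0 - w) * crystalline


def aggregate_variety(
    variety_id: str,
    records: Sequence[FieldRecord],
    chalky_fraction_pct: float,
    weighted: bool = True,
) -> VarietyMorphometry:
    """Aggregate field summaries into one per-variety row.

    Fields are averaged within each grain, grain means are averaged per
    endosperm region, and the variety value mixes the chalky and
    crystalline region means weighted by the externally supplied chalky
    fraction of the endosperm (a visual estimate, in %).  Untagged fields
    are treated as crystalline when no tagged crystalline fields exist.
    The weighting applies to porosity and all shape means alike; pass
    ``weighted=False`` to pool every field regardless of region.
    """
    if not records:
        raise ValueError("at least one field record is required")
    if not 0.0 <= chalky_fraction_pct <= 100.0:
        raise ValueError("chalky_fraction_pct must be in [0, 100]")

    chalky = [r for r in records if r.region_tag == "chalky"]
    crystalline = [r for r in records if r.region_tag != "chalky"]
    if chalky_fraction_pct > 0 and weighted and not chalky:
        raise ValueError(
            "region/weight mismatch: chalky_fraction > 0 but no chalky-tagged fields"
        )

    attrs = ["porosity_pct", "mean_area_um2", "mean_eccentricity", "mean_circularity"]
    values: dict[str, float] = {}
    sds: dict[str, float] = {}
    if not weighted or not chalky or not crystalline:
        pool = records if (not weighted or not crystalline) else crystalline
        if weighted and chalky and not crystalline:
            pool = chalky
        for a in attrs:
            values[a], sds[a], n_grains, n_fields = _grain_then_variety_mean(pool, a)
    else:
        w = chalky_fraction_pct / 100.0
        for a in attrs:
            mc, sc, _, _ = _grain_then_variety_mean(chalky, a)
            mx, sx, _, _ = _grain_then_variety_mean(crystalline, a)
            values[a] = _weighted(mc, mx, chalky_fraction_pct)
            # propagate across-grain sds through the fixed-weight combination
            if np.isfinite(sc) and np.isfinite(sx):
                sds[a] = math.sqrt((w * sc) ** 2 + ((1 - w) * sx) ** 2)
            else:
                sds[a] = sc if np.isfinite(sc) else sx
        n_grains = len({r.grain_id for r in records})
        n_fields = len(records)

    mean_area = values["mean_area_um2"]
    diam = equivalent_diameter(mean_area) if np.isfinite(mean_area) and mean_area > 0 else float("nan")
    return VarietyMorphometry(
        variety_id=variety_id,
        mean_area_um2=mean_area,
        sd_area_um2=sds["mean_area_um2"],
        mean_eccentricity=values["mean_eccentricity"],
        mean_circularity=values["mean_circularity"],
        estimated_diameter_um=diam,
        mean_porosity_pct=values["porosity_pct"],
        sd_porosity_pct=sds["porosity_pct"],
        chalky_fraction_pct=chalky_fraction_pct,
        n_grains=n_grains,
        n_fields=n_fields,
    )
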