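"""Ground-truthed synthetic micrographs and glycemic curves.

The study's raw FESEM micrographs and human glucose curves are not
deposited, so every pipeline stage is exercised against synthetic inputs
that emulate their statistical structure:

* micrographs of compound starch granules — polygonal granules a few um
  across packed into a grain section, realised as an (anisotropic) Voronoi
  tessellation whose cells are pulled apart to a programmed void fraction,
  with perspective shadows rendered as monotone intensity ramps filling
  the gaps on the fixed illumination side of granule edges;
* glycemic curves on the standard 8-point grid with a fasting baseline, a
  30-45 min peak, return toward baseline by 120 min, inter-subject
  variability, and a programmed GI realised exactly in the noise-free limit.

Every generator is a pure function of its seed and parameters, and ground
truth is recorded before noise, so recovery error is attributable to the
analysis rather than the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glycemia import STANDARD_TIMES_MIN
from .morphometry import Micrograph

__all__ = [
    "MicrographParams",
    "MicrographGroundTruth",
    "CurveParams",
    "CurveGroundTruth",
    "generate_micrograph",
    "generate_glycemic_curves",
]


# ---------------------------------------------------------------------------
# micrographs
# ---------------------------------------------------------------------------


@dataclass
class MicrographParams:
    """Study conditions for one synthetic endosperm field.

    The defaults emulate a 5000X field: 384 px square at 0.05 um/px
    (a 19.2 um window), ~60 granule wedges of 2-4 um across, porosity in
    the observed 0.4-6.7 % range, flat granule interiors with Gaussian
    noise, and shadows in gap segments whose boundary normal is aligned
    with the illumination azimuth.
    """

    shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 0.05
    n_granules: int = 60
    target_porosity_pct: float = 4.0
    # per-granule elongation: aspect ratio a/b is lognormal
    log_aspect_mean: float = math.log(1.5)
    log_aspect_sd: float = 0.25
    # rendering
    granule_intensity: float = 0.75
    pore_intensity: float = 0.15
    granule_jitter: float = 0.04
    noise_sd: float = 0.05
    shadows: bool = True
    illumination_deg: float = 35.0  # azimuth of the light direction
    shadow_edge_max_angle_deg: float = 40.0
    shadow_ramp_floor: float = 0.35  # darkest ramp point, as fraction of pore->granule


@dataclass
class MicrographGroundTruth:
    """What the generator actually drew, before noise."""

    granule_labels: np.ndarray  # instance map, 0 = void
    pore_mask: np.ndarray
    shadow_mask: np.ndarray
    granule_areas_um2: np.ndarray  # per instance, index label-1
    granule_aspects: np.ndarray
    granule_orientations_rad: np.ndarray
    programmed_porosity_pct: float
    achieved_porosity_pct: float
    gap_metric_px: float


def _anisotropic_distances(
    shape: tuple[int, int],
    centers: np.ndarray,
    aspects: np.ndarray,
    thetas: np.ndarray,
) -> np.ndarray:
    """Stack of per-seed elliptic distances (metric units ~ px)."""
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), indexing="ij"
    )
    out = np.empty((len(centers),) + shape, dtype=np.float32)
    for i, (cy, cx) in enumerate(centers):
        dy, dx = rr - cy, cc - cx
        ct, st = math.cos(thetas[i]), math.sin(thetas[i])
        u = dx * ct + dy * st  # along the long axis
        v = -dx * st + dy * ct
        a = math.sqrt(aspects[i])  # area-preserving stretch
        out[i] = np.sqrt((u / a) ** 2 + (v * a) ** 2)
    return out


def generate_micrograph(
    params: MicrographParams | None = None, seed: int = 0
) -> tuple[Micrograph, MicrographGroundTruth]:
    """Render one synthetic endosperm field with full ground truth.

    Granules are the cells of an anisotropic Voronoi tessellation of
    ``n_granules`` seeded centres; a pixel is void when the difference of
    its two smallest centre distances falls below a gap width, which is
    bisected until the *pore* fraction (void minus shadows) matches the
    programmed porosity.  Shadow gaps (those whose orientation faces the
    illumination azimuth, when shadows are on) are rendered as a monotone
    ramp from dark at the occluding granule edge to granule brightness at
    the far edge.  Same seed, same parameters -> bit-identical output.

    Raises
    ------
    ValueError
        If the porosity target is outside [0, 50) or cannot be realised
        with the requested packing.
    """
    params = params or MicrographParams()
    if not 0.0 <= params.target_porosity_pct < 50.0:
        raise ValueError("target_porosity_pct must be in [0, 50)")
    rng = np.random.default_rng(seed)
    H, W = params.shape
    n = params.n_granules
    centers = np.column_stack([rng.uniform(0, H, n), rng.uniform(0, W, n)])
    aspects = np.exp(rng.normal(params.log_aspect_mean, params.log_aspect_sd, n))
    thetas = rng.uniform(0, math.pi, n)

    dists = _anisotropic_distances((H, W), centers, aspects, thetas)
    order = np.argsort(dists, axis=0)
    i1, i2 = order[0], order[1]
    flat = dists.reshape(n, -1)
    cols = np.arange(H * W)
    d1 = flat[i1.ravel(), cols].reshape(H, W).astype(float)
    d2 = flat[i2.ravel(), cols].reshape(H, W).astype(float)
    margin = d2 - d1  # 0 on a cell boundary, grows into the cell interior

    # which gap segments would be shadowed (independent of the gap width)
    phi = math.radians(params.illumination_deg)
    illum = np.array([math.sin(phi), math.cos(phi)])  # (dy, dx), unit
    edge_vec = centers[i2] - centers[i1]  # (H, W, 2) across the local boundary
    edge_len = np.linalg.norm(edge_vec, axis=-1)
    edge_len[edge_len == 0] = 1.0
    align = np.abs((edge_vec @ illum) / edge_len)
    shadow_pair = params.shadows & (
        align > math.cos(math.radians(params.shadow_edge_max_angle_deg))
    )

    target = params.target_porosity_pct / 100.0
    if target == 0.0:
        gap = 0.0
        void = np.zeros((H, W), dtype=bool)
    else:
        lo, hi = 0.0, float(margin.max())
        if ((margin < hi) & ~shadow_pair).mean() < target:
            raise ValueError("infeasible packing: porosity target cannot be reached")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            frac = ((margin < mid) & ~shadow_pair).mean()
            if frac < target:
                lo = mid
            else:
                hi = mid
        gap = hi
        void = margin < gap

    shadow_mask = void & shadow_pair
    pore_mask = void & ~shadow_pair
    labels = np.where(void, 0, i1 + 1)

    areas_px = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    truth = MicrographGroundTruth(
        granule_labels=labels,
        pore_mask=pore_mask,
        shadow_mask=shadow_mask,
        granule_areas_um2=areas_px * params.pixel_size_um**2,
        granule_aspects=aspects,
        granule_orientations_rad=thetas,
        programmed_porosity_pct=params.target_porosity_pct,
        achieved_porosity_pct=100.0 * pore_mask.mean(),
        gap_metric_px=gap,
    )

    # render intensities
    img = np.full((H, W), params.pore_intensity)
    jitter = rng.uniform(-params.granule_jitter, params.granule_jitter, n)
    granule = labels > 0
    img[granule] = params.granule_intensity + jitter[labels[granule] - 1]
    if shadow_mask.any():
        # t: 0 at the occluding (upstream) granule edge, 1 at the far edge
        upstream_is_i1 = ((centers[i1] - centers[i2]) @ -illum) > 0
        s = np.zeros_like(margin)
        if gap > 0:
            s = np.clip(margin / gap, 0.0, 1.0)
        t = np.where(upstream_is_i1, (1.0 - s) / 2.0, (1.0 + s) / 2.0)
        span = params.granule_intensity - params.pore_intensity
        ramp = params.pore_intensity + (
            params.shadow_ramp_floor + (1.0 - params.shadow_ramp_floor) * t
        ) * span
        img[shadow_mask] = ramp[shadow_mask]
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, (H, W))
    img = np.clip(img, 0.0, 1.0)

    micro = Micrograph(
        pixels=img,
        pixel_size=params.pixel_size_um,
        magnification=5000,
        variety_id="synthetic",
        field_id=f"seed{seed}",
        region_tag="unknown",
    )
    return micro, truth


# ---------------------------------------------------------------------------
# glycemic curves
# ---------------------------------------------------------------------------


@dataclass
class CurveParams:
    """Study conditions for a simulated GI trial.

    Defaults mirror the in-vivo design: 10 healthy subjects, 3 repetitions
    of the glucose reference, sampling at -5/0/15/30/45/60/90/120 min,
    fasting baseline below the 5.5 mmol/L inclusion cut-off, a glucose
    peak of ~3.3 mmol/L above baseline at 30-45 min decaying back toward
    baseline by 120 min, and measurement noise of 0.15 mmol/L (a ~3 %
    glucometer CV at the fasting level).
    """

    n_subjects: int = 10
    reference_repetitions: int = 3
    reference_id: str = "glucose_ref"
    baseline_mean: float = 4.8
    baseline_sd: float = 0.3
    peak_height_mean: float = 3.3
    peak_height_sd: float = 0.6
    peak_times_min: tuple[float, ...] = (30.0, 45.0)
    noise_sd: float = 0.15
    times_min: tuple[float, ...] = STANDARD_TIMES_MIN


@dataclass
class CurveGroundTruth:
    """Programmed trial parameters plus the per-subject noise-free profiles."""

    programmed_gi: dict[str, float]
    params: CurveParams
    seed: int
    subject_baselines: np.ndarray = field(default_factory=lambda: np.array([]))
    subject_peak_heights: np.ndarray = field(default_factory=lambda: np.array([]))
    subject_peak_times: np.ndarray = field(default_factory=lambda: np.array([]))


def _excursion(times: np.ndarray, peak_height: float, peak_time: float) -> np.ndarray:
    """Piecewise-linear rise to a single peak, then exponential-like decay.

    The decay constant is set so the excursion has fallen to ~5 % of the
    peak by 120 min (return toward baseline by the end of the test).
    """
    e = np.zeros_like(times)
    rise = (times >= 0) & (times <= peak_time)
    e[rise] = peak_height * times[rise] / peak_time
    tau = (120.0 - peak_time) / 3.0
    fall = times > peak_time
    e[fall] = peak_height * np.exp(-(times[fall] - peak_time) / tau)
    return e


def generate_glycemic_curves(
    programmed_gi: dict[str, float],
    params: CurveParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, CurveGroundTruth]:
    """Simulate a GI trial; returns a long curve table plus ground truth.

    Each subject draws a fasting baseline, a reference peak height and a
    peak time; every reference repetition shares the subject's noise-free
    profile, and each test food's excursion is that profile scaled by
    programmed GI / 100, so with ``noise_sd = 0`` the per-subject GI of
    every food equals its programmed GI exactly.  Additive measurement
    noise is applied last (glucose floored at 0.5 mmol/L).

    The table has columns subject_id, food_id, repetition, time_min,
    glucose_mmol_l — the long format the GI pipeline consumes.
    """
    params = params or CurveParams()
    if params.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if any(g <= 0 for g in programmed_gi.values()):
        raise ValueError("programmed GI values must be positive")

    rng = np.random.default_rng(seed)
    times = np.asarray(params.times_min, dtype=float)
    baselines = rng.normal(params.baseline_mean, params.baseline_sd, params.n_subjects)
    baselines = np.clip(baselines, 3.5, 5.4)  # healthy fasting range
    heights = rng.normal(params.peak_height_mean, params.peak_height_sd, params.n_subjects)
    heights = np.clip(heights, 1.0, None)
    peak_times = rng.choice(params.peak_times_min, params.n_subjects)

    rows: list[dict] = []

    def emit(subj: int, food: str, rep: int, profile: np.ndarray) -> None:
        noisy = profile + rng.normal(0.0, params.noise_sd, profile.size) \
            if params.noise_sd > 0 else profile
        noisy = np.maximum(noisy, 0.5)
        for t, gl in zip(times, noisy):
            rows.append(
                {"subject_id": f"S{subj + 1:02d}", "food_id": food, "repetition": rep,
                 "time_min": t, "glucose_mmol_l": float(gl)}
            )

    for s in range(params.n_subjects):
        ref_profile = baselines[s] + _excursion(times, heights[s], peak_times[s])
        for rep in range(1, params.reference_repetitions + 1):
            emit(s, params.reference_id, rep, ref_profile)
        for food, gi in programmed_gi.items():
            profile = baselines[s] + (gi / 100.0) * _excursion(
                times, heights[s], peak_times[s]
            )
            emit(s, food, 1, profile)

    truth = CurveGroundTruth(
        programmed_gi=dict(programmed_gi),
        params=params,
        seed=seed,
        subject_baselines=baselines,
        subject_peak_heights=heights,
        subject_peak_times=peak_times,
    )
    return pd.DataFrame(rows), truth
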