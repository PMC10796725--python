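"""In-vivo Glycemic Index from capillary blood-glucose curves.

A trial follows the ISO 26642 design: each subject eats a 50 g available
carbohydrate portion of a test food (or the glucose reference, repeated),
and capillary glucose (mmol/L) is sampled at -5 and 0 min fasting and at
15, 30, 45, 60, 90 and 120 min postprandially.  The food's response is the
incremental area under the curve (IAUC) above the fasting baseline,
disregarding area below baseline; per subject,

    GI = 100 * IAUC(test food) / mean IAUC(glucose reference),

and the study GI of a food is the arithmetic mean over subjects.  Foods are
classed low (GI <= 55), medium (56-69) or high (GI >= 70).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_TIMES_MIN",
    "GlycemicCurve",
    "IaucResult",
    "GITrialResult",
    "NonResponderError",
    "baseline",
    "iauc",
    "subject_gi",
    "study_gi",
    "classify_gi",
    "gi_table",
]

STANDARD_TIMES_MIN: tuple[float, ...] = (-5.0, 0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)

GIClass = Literal["low", "medium", "high"]


class NonResponderError(ValueError):
    """A subject whose mean reference IAUC is not positive; excluded from the study mean."""


@dataclass
class GlycemicCurve:
    """One subject-food blood-glucose time series.

    ``times`` are minutes relative to the first bite (fasting samples at
    t <= 0); ``glucose`` is whole-blood glucose in mmol/L.
    """

    subject_id: str
    food_id: str
    times: Sequence[float] = STANDARD_TIMES_MIN
    glucose: Sequence[float] = ()
    repetition: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.glucose > 0):
            raise ValueError("glucose values must be positive (mmol/L)")
        if (self.times <= 0).sum() < 1:
            raise ValueError("at least one fasting sample (t <= 0) is required")


@dataclass
class IaucResult:
    """Incremental area under the curve above baseline (mmol*min/L)."""

    iauc: float
    baseline: float


@dataclass
class GITrialResult:
    """Study-level GI for one food: per-subject values, mean, sd and class."""

    food_id: str
    per_subject_gi: list[float]
    study_gi_mean: float
    study_gi_sd: float
    gi_class: GIClass
    n_subjects: int
    excluded_subjects: list[str] = field(default_factory=list)


def baseline(curve: GlycemicCurve) -> float:
    """Fasting baseline: the mean of all samples at t <= 0 (mmol/L)."""
    fasting = curve.glucose[curve.times <= 0]
    return float(fasting.mean())


def iauc(curve: GlycemicCurve) -> IaucResult:
    """Trapezoidal incremental AUC above baseline over t >= 0.

    Sums trapezoid areas of max(glucose - baseline, 0) between consecutive
    post-baseline time points.  A segment that crosses the baseline is split
    at the linearly interpolated crossing time, so only the portion above
    baseline contributes; area below baseline is disregarded.
    """
    b = baseline(curve)
    keep = curve.times >= 0
    t = curve.times[keep]
    g = curve.glucose[keep]
    if t.size < 2:
        raise ValueError("at least 2 time points at t >= 0 are required")
    total = 0.0
    for i in range(t.size - 1):
        y0, y1 = g[i] - b, g[i + 1] - b
        dt = t[i + 1] - t[i]
        if y0 >= 0 and y1 >= 0:
            total += 0.5 * (y0 + y1) * dt
        elif y0 < 0 and y1 < 0:
            continue
        else:
            # one endpoint above baseline: triangle on that side of the crossing
            frac_above = abs(max(y0, y1)) / (abs(y0) + abs(y1))
            total += 0.5 * max(y0, y1) * dt * frac_above
    return IaucResult(iauc=float(total), baseline=b)


def subject_gi(test: IaucResult, reference_iaucs: Sequence[IaucResult]) -> float:
    """Per-subject GI: 100 x test IAUC over the mean reference IAUC."""
    if len(reference_iaucs) < 1:
        raise ValueError("at least one reference repetition is required")
    mean_ref = float(np.mean([r.iauc for r in reference_iaucs]))
    if mean_ref <= 0:
        raise NonResponderError("mean reference IAUC is not positive")
    return 100.0 * test.iauc / mean_ref


def study_gi(
    per_subject: Sequence[float],
    food_id: str = "",
    excluded_subjects: Sequence[str] = (),
) -> GITrialResult:
    """Study GI: arithmetic mean over subjects with sample (n-1) sd.

    With a single subject the sd is undefined and reported as NaN.
    """
    vals = [float(v) for v in per_subject]
    if not vals:
        raise ValueError("per_subject GI list must not be empty")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return GITrialResult(
        food_id=food_id,
        per_subject_gi=vals,
        study_gi_mean=mean,
        study_gi_sd=sd,
        gi_class=classify_gi(mean),
        n_subjects=len(vals),
        excluded_subjects=list(excluded_subjects),
    )


def classify_gi(gi: float) -> GIClass:
    """Class from the conventional cut-offs: <=55 low, >=70 high, else medium."""
    if gi < 0:
        raise ValueError("GI must be non-negative")
    if gi <= 55.0:
        return "low"
    if gi >= 70.0:
        return "high"
    return "medium"


def gi_table(curves: pd.DataFrame, reference: str = "glucose_ref") -> pd.DataFrame:
    """Study GI table from a long-format curve table.

    ``curves`` needs columns subject_id, food_id, repetition, time_min,
    glucose_mmol_l.  Rows with ``food_id == reference`` are the reference
    repetitions.  Subjects with non-positive mean reference IAUC are
    excluded from every food's mean (non-responders).  Returns one row per
    test food: food_id, gi_mean, gi_sd, gi_class, n_subjects.
    """
    required = {"subject_id", "food_id", "repetition", "time_min", "glucose_mmol_l"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table is missing columns: {sorted(missing)}")

    ref_iauc: dict[str, list[IaucResult]] = {}
    test_iauc: dict[tuple[str, str], IaucResult] = {}
    for (subj, food, rep), grp in curves.groupby(["subject_id", "food_id", "repetition"]):
        grp = grp.sort_values("time_min")
        curve = GlycemicCurve(
            subject_id=str(subj), food_id=str(food),
            times=grp["time_min"].to_numpy(), glucose=grp["glucose_mmol_l"].to_numpy(),
            repetition=int(rep),
        )
        res = iauc(curve)
        if food == reference:
            ref_iauc.setdefault(str(subj), []).append(res)
        else:
            test_iauc[(str(subj), str(food))] = res

    rows = []
    foods = sorted({f for (_, f) in test_iauc})
    for food in foods:
        per_subject, excluded = [], []
        for subj in sorted(ref_iauc):
            if (subj, food) not in test_iauc:
                continue
            try:
                per_subject.append(subject_gi(test_iauc[(subj, food)], ref_iauc[subj]))
            except NonResponderError:
                excluded.append(subj)
        res = study_gi(per_subject, food_id=food, excluded_subjects=excluded)
        rows.append(
            {"food_id": food, "gi_mean": res.study_gi_mean, "gi_sd": res.study_gi_sd,
             "gi_class": res.gi_class, "n_subjects": res.n_subjects}
        )
    return pd.DataFrame(rows)
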