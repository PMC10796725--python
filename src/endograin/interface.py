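"""Run configuration and the end-to-end fixture reproduction report.

``reproduce_tables`` recomputes everything in the packaged per-variety
tables that the pipeline's own primitives can derive from the printed
cells: every estimated granule diameter from its mean area, the GI class
counts under the conventional cut-offs, the headline GI range, and the
named structure/composition correlations — and reports pass/fail per
check against the printed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, fields as dc_fields
from typing import Any

import yaml

from .glycemia import classify_gi
from .morphometry import equivalent_diameter
from .stats_explore import correlation_report
from .tables import load_table3, load_table4, verify_fixture_checksums

__all__ = ["RunConfig", "load_config", "reproduce_tables"]


@dataclass
class RunConfig:
    """Effective settings for a pipeline run (YAML-loadable).

    Unknown keys are rejected; every threshold is echoed by the CLI log so
    a run is reproducible from its configuration and seed alone.
    """

    seed: int = 0
    segmentation: dict[str, Any] = dc_field(default_factory=dict)
    voids: dict[str, Any] = dc_field(default_factory=dict)
    gi: dict[str, Any] = dc_field(default_factory=dict)
    correlations: dict[str, Any] = dc_field(default_factory=dict)
    pca: dict[str, Any] = dc_field(default_factory=dict)
    simulate: dict[str, Any] = dc_field(default_factory=dict)
    paths: dict[str, Any] = dc_field(default_factory=dict)


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def reproduce_tables(diameter_tol_um: float = 0.01, r_tol: float = 0.02) -> dict:
    """Recompute the printed-table derivations and report pass/fail.

    Returns a dict with sections ``diameters`` (per-panel match counts and
    the worst deviation), ``gi_classes`` (class counts and headline range)
    and ``correlations`` (recomputed vs printed r per named pair).
    Fixture checksums are verified first; a mismatch aborts.
    """
    verify_fixture_checksums()
    t3, t4 = load_table3(), load_table4()

    diameters: dict[str, Any] = {}
    for name, tbl in (("table3", t3), ("table4", t4)):
        rows = tbl.dropna(subset=["area_um2", "diameter_um"])
        devs = {
            v: abs(equivalent_diameter(r_.area_um2) - r_.diameter_um)
            for v, r_ in rows.iterrows()
        }
        diameters[name] = {
            "n_printed": len(rows),
            "n_matched": sum(d <= diameter_tol_um + 1e-9 for d in devs.values()),
            "max_abs_dev_um": max(devs.values()) if devs else 0.0,
        }
        diameters[name]["pass"] = diameters[name]["n_matched"] == diameters[name]["n_printed"]

    gi = t3["gi_mean"].astype(float)
    classes = gi.map(classify_gi)
    counts = classes.value_counts().to_dict()
    printed = t3["gi_class"]
    gi_section = {
        "counts": {c: int(counts.get(c, 0)) for c in ("high", "medium", "low")},
        "agrees_with_printed_grouping": bool((classes == printed).all()),
        "max_gi_rounded": int(round(gi.max())),
        "min_gi_rounded": int(round(gi.min())),
        "pass": counts.get("high", 0) == 10 and counts.get("medium", 0) == 10
        and counts.get("low", 0) == 5,
    }

    correlations = []
    for res in correlation_report(t3, t4):
        entry = {
            "pair": f"{res.x} ~ {res.y}",
            "subset": res.subset,
            "n": res.n,
            "r": res.r,
            "printed_r": res.expected,
        }
        if res.r is not None and res.expected is not None:
            entry["abs_dev"] = abs(res.r - res.expected)
            entry["within_tol"] = entry["abs_dev"] <= r_tol
        correlations.append(entry)

    return {"diameters": diameters, "gi_classes": gi_section, "correlations": correlations}
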