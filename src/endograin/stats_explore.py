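"""Correlation and PCA exploration of variety-level feature tables.

The feature tables are pandas DataFrames indexed by variety, one named
variable per column, with missing cells as NaN (never silent zeros).
Correlations use pairwise-complete observations; PCA drops any variety
with a missing retained variable (listwise), autoscales the remainder
(zero mean, unit variance per column) and decomposes by SVD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "AutoscaleRecord",
    "PcaModel",
    "pairwise_pearson",
    "autoscale",
    "pca",
    "correlation_report",
]


@dataclass
class CorrelationResult:
    """Pearson r for a named variable pair over a named subset."""

    x: str
    y: str
    r: float | None  # None: undefined (constant column or n < 3)
    n: int
    subset: str = "all"
    expected: float | None = None  # externally reported value, if any

    @property
    def defined(self) -> bool:
        return self.r is not None


def pairwise_pearson(
    table: pd.DataFrame,
    x: str,
    y: str,
    subset: pd.Index | list[str] | None = None,
    subset_name: str = "all",
) -> CorrelationResult:
    """Pearson r between two columns with pairwise-complete deletion.

    A constant column (or fewer than 3 complete pairs) gives an undefined
    result (``r is None``), never a silent number.
    """
    df = table.loc[subset] if subset is not None else table
    pair = df[[x, y]].dropna()
    n = len(pair)
    if n < 3:
        return CorrelationResult(x, y, None, n, subset_name)
    xs, ys = pair[x].to_numpy(float), pair[y].to_numpy(float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(x, y, None, n, subset_name)
    r = float(stats.pearsonr(xs, ys).statistic)
    return CorrelationResult(x, y, r, n, subset_name)


@dataclass
class AutoscaleRecord:
    """Column means and sds applied by :func:`autoscale`."""

    means: pd.Series
    sds: pd.Series


def autoscale(table: pd.DataFrame) -> tuple[pd.DataFrame, AutoscaleRecord]:
    """Unit-variance scaling: each column to mean 0, sd 1 over non-missing rows.

    Uses the sample (n-1) standard deviation, the chemometric convention.
    Constant columns cannot be scaled and are rejected by name.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        raise ValueError(f"cannot autoscale constant column(s): {constant}")
    scaled = (table - means) / sds
    return scaled, AutoscaleRecord(means=means, sds=sds)


@dataclass
class PcaModel:
    """Scores, loadings and explained variance of an autoscaled PCA.

    ``scores @ loadings.T`` reconstructs the autoscaled matrix when all
    components are kept.  Loadings columns are orthonormal; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """

    scores: pd.DataFrame  # varieties x components
    loadings: pd.DataFrame  # variables x components
    explained_variance_pct: np.ndarray
    preprocessing: AutoscaleRecord
    n_rows_dropped: int = 0
    dropped_rows: list[str] = field(default_factory=list)


def pca(table: pd.DataFrame, n_components: int | None = None) -> PcaModel:
    """PCA of the autoscaled table via singular-value decomposition.

    Rows with any missing retained variable are dropped first (their labels
    are recorded on the model).  Requesting more components than the rank
    of the centred matrix is rejected.
    """
    complete = table.dropna()
    dropped = [str(i) for i in table.index.difference(complete.index)]
    scaled, record = autoscale(complete)
    X = scaled.to_numpy(float)
    rank = int(np.linalg.matrix_rank(X))
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # fix signs: largest-magnitude loading of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    var = s**2 / (X.shape[0] - 1)
    explained = 100.0 * var / var.sum()
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * s[:n_components]), index=complete.index, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=table.columns, columns=comp_names)
    return PcaModel(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=explained[:n_components],
        preprocessing=record,
        n_rows_dropped=len(dropped),
        dropped_rows=dropped,
    )


def correlation_report(
    table3: pd.DataFrame, table4: pd.DataFrame
) -> list[CorrelationResult]:
    """The study's named structure/composition correlations.

    Recomputes each reported variable pair on its stated subset from the
    per-variety tables: porosity vs mean granule area over all
    area-bearing varieties; total fat vs GI over the non-waxy GI panel;
    ashes vs eccentricity with and without Valente (the high-ash outlier);
    amylose vs GI; circularity vs area overall and for Italian varieties;
    estimated diameter vs ashes.  The ``expected`` attribute carries the
    study's printed r for comparison.
    """
    merged = pd.concat(
        [
            table3[["area_um2", "eccentricity", "circularity", "porosity_pct"]],
            table4[["area_um2", "eccentricity", "circularity", "porosity_pct"]],
        ]
    )
    nonwaxy3 = table3.index[table3["waxy"] == 0]
    no_valente = [v for v in table3.index if v != "Valente"]
    italian = list(table3.index) + list(table4.index[table4["origin"] == "italian"])

    out = [
        pairwise_pearson(merged, "area_um2", "porosity_pct", subset_name="area-bearing varieties, both panels"),
        pairwise_pearson(table3, "fat_g", "gi_mean", nonwaxy3, "non-waxy GI panel"),
        pairwise_pearson(table3, "ashes_g", "eccentricity", subset_name="GI panel"),
        pairwise_pearson(table3, "ashes_g", "eccentricity", no_valente, "GI panel without Valente"),
        pairwise_pearson(table3, "amylose_pct", "gi_mean", subset_name="GI panel"),
        pairwise_pearson(merged, "circularity", "area_um2", subset_name="both panels"),
        pairwise_pearson(
            pd.concat([table3, table4]).loc[lambda d: d.index.isin(italian)],
            "circularity", "area_um2", subset_name="Italian varieties",
        ),
        pairwise_pearson(table3, "diameter_um", "ashes_g", subset_name="GI panel"),
    ]
    printed = [-0.5822, -0.3265, 0.5181, 0.5216, -0.5088, 0.4562, 0.4872, -0.5397]
    for res, exp in zip(out, printed):
        res.expected = exp
    return out
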