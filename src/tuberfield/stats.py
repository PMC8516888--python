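"""Replicate summaries, Pearson correlation and paired t-tests.

The statistical layer mirrors the analysis conventions of the
experiments this package emulates: results reported as mean +/- sample
standard deviation over replicates, two-tailed Pearson correlation
p-values from the t transform with n-2 degrees of freedom, two-tailed
paired Student's t-tests with the usual star annotation
(* p<0.05, ** p<0.01, *** p<0.001), and an all-pairs correlation heat
map over melanin area, TTC white area, TTC red area, current and
conductivity change ratio.

No multiple-testing correction is applied, matching the convention of
the workflow being reproduced; this is stated rather than hidden.
Correlations default to replicate-level points; condition-mean
aggregation is available via ``aggregate="condition"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "DegenerateDataError",
    "pearson",
    "paired_ttest",
    "summarize_reps",
    "correlation_heatmap",
    "heatmap_to_png",
    "MEASUREMENT_VARIABLES",
]

#: Variables correlated in the standard heat map, in display order.
MEASUREMENT_VARIABLES = (
    "melanin_area_cm2",
    "ttc_white_area_cm2",
    "ttc_red_area_cm2",
    "current_A",
    "conductivity_ratio",
)

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class DegenerateDataError(ValueError):
    """Zero-variance input that makes the statistic undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    stars: str
    n: int


def stars_for_p(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-tailed p-value.

    The p-value refers ``t = r sqrt(n-2) / sqrt(1-r^2)`` to the t
    distribution with n-2 degrees of freedom.

    Raises
    ------
    DegenerateDataError
        If either vector has zero variance (correlation undefined).
    ValueError
        On unequal lengths or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance makes correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def paired_ttest(x, y) -> TTestResult:
    """Two-tailed paired Student's t-test on differences x - y.

    Raises
    ------
    DegenerateDataError
        If the differences have zero variance (t undefined), including
        the x == y case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateDataError(
            "paired differences have zero variance; t statistic undefined"
        )
    res = sps.ttest_rel(x, y)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), p=p, stars=stars_for_p(p), n=n)


def summarize_reps(values) -> tuple[float, float | None]:
    """Mean and sample standard deviation (n-1); sd is None for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty replicate set")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return mean, sd


def correlation_heatmap(
    table: pd.DataFrame,
    variables=MEASUREMENT_VARIABLES,
    aggregate: str = "replicate",
) -> pd.DataFrame:
    """All-pairs Pearson correlation matrix over measurement variables.

    Parameters
    ----------
    table : DataFrame
        Wide measurement table: one row per (condition, replicate) with
        the variable columns present.
    aggregate : {"replicate", "condition"}
        "replicate" correlates replicate-level points; "condition"
        averages replicates per condition first.

    Returns
    -------
    DataFrame with a row per ordered variable pair, columns
    (var_i, var_j, r, p, n); diagonal cells carry r = 1, p = 0 by
    convention.  Use :func:`pivot_r` for the square r matrix.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks variable columns: {missing}")
    if aggregate == "condition":
        data = table.groupby("condition_id", sort=True)[variables].mean()
    elif aggregate == "replicate":
        data = table[variables]
    else:
        raise ValueError("aggregate must be 'replicate' or 'condition'")
    if len(data) < 3:
        raise ValueError("need at least 3 points for correlation")

    rows = []
    for vi in variables:
        for vj in variables:
            if vi == vj:
                rows.append({"var_i": vi, "var_j": vj, "r": 1.0, "p": 0.0,
                             "n": len(data)})
            else:
                res = pearson(data[vi].to_numpy(), data[vj].to_numpy())
                rows.append({"var_i": vi, "var_j": vj, "r": res.r, "p": res.p,
                             "n": res.n})
    return pd.DataFrame(rows)


def pivot_r(heatmap_table: pd.DataFrame) -> pd.DataFrame:
    """Square r matrix from the long-form heat-map table."""
    return heatmap_table.pivot(index="var_i", columns="var_j", values="r")


def heatmap_to_png(heatmap_table: pd.DataFrame, path) -> None:
    """Render the correlation matrix to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = pivot_r(heatmap_table)
    order = [v for v in MEASUREMENT_VARIABLES if v in mat.index]
    if order:
        mat = mat.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat.index)), mat.index)
    for i in range(len(mat.index)):
        for j in range(len(mat.columns)):
            ax.text(j, i, f"{mat.iat[i, j]:.2f}", ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
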