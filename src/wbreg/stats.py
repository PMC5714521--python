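"""Cohort summaries in box-and-whisker convention.

Quartiles use the linear-interpolation percentile convention; outliers
are values beyond 1.5 x IQR from the quartiles; whiskers are the min/max
of the population after outlier elimination; the notch half-width is the
McGill 95% median confidence rule

    delta = 1.57 * IQR / sqrt(n).

Cohort tables follow the Minimum / 1st Quartile / Median +- delta /
3rd Quartile / Maximum column layout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSummary", "summarize", "cohort_table", "boxplot"]


@dataclass
class CohortSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    delta: float
    n: int
    outliers: list = field(default_factory=list)


def summarize(values) -> CohortSummary:
    """Five-number summary with 1.5·IQR outlier fences and median notch."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("summarize needs at least one non-NaN value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    kept = v[(v >= lo_fence) & (v <= hi_fence)]
    delta = 1.57 * iqr / np.sqrt(v.size)
    return CohortSummary(
        minimum=float(kept.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(kept.max()),
        delta=float(delta),
        n=int(v.size),
        outliers=sorted(float(x) for x in outliers),
    )


def cohort_table(frame: pd.DataFrame, metrics=None, by: str = "region") -> pd.DataFrame:
    """One summary row per group x metric from a tidy per-case metric frame.

    NaN entries (regions missing in some cases) are excluded from their
    row with a correspondingly reduced n.  Percentile convention: linear
    interpolation between order statistics (recorded in the table attrs,
    since quartiles depend on it).
    """
    if metrics is None:
        metrics = [c for c in ("TO", "DC", "JC", "FN", "FP", "VS", "HD", "DE")
                   if c in frame.columns]
    rows = []
    for group, sub in frame.groupby(by, sort=True):
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy()
            if vals.size == 0:
                continue
            s = summarize(vals)
            rows.append(
                {
                    by: group,
                    "metric": metric,
                    "Minimum": s.minimum,
                    "1st Quartile": s.q1,
                    "Median": s.median,
                    "Delta": s.delta,
                    "3rd Quartile": s.q3,
                    "Maximum": s.maximum,
                    "n": s.n,
                    "outliers": len(s.outliers),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["percentile_convention"] = "linear interpolation"
    table.attrs["notch"] = "delta = 1.57*IQR/sqrt(n), 95% median confidence"
    return table


def boxplot(frame: pd.DataFrame, metric: str, by: str = "region", path=None):
    """Optional box-whisker rendering (requires matplotlib); returns the axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(frame[by].unique())
    data = [frame.loc[frame[by] == g, metric].dropna().to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot(data, notch=True, whis=1.5, labels=groups, sym="r+")
    ax.set_ylabel(metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
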