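"""Group comparisons (one-tailed unpaired Student's t) and per-cell summaries.

Group data are reported as mean ± SEM.  The default test is the classical
pooled-variance Student's t for unpaired samples with a one-tailed p-value in
a caller-stated direction; Welch's unequal-variance form is available behind
a flag.  Significance stars follow *p < 0.05, **p < 0.01, ***p < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_one_tailed: float
    significance_stars: str
    direction: str
    welch: bool
    degenerate: bool = False  # zero variance in both groups with equal means


def significance_stars(p: float) -> str:
    """Star map: p < 0.001 → ***, p < 0.01 → **, p < 0.05 → *, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_a,
    values_b,
    direction: str = "a_greater",
    group_a: str = "A",
    group_b: str = "B",
    welch: bool = False,
) -> GroupComparison:
    """One-tailed unpaired two-sample t-test.

    ``direction`` states the alternative hypothesis: "a_greater" tests
    mean(a) > mean(b), "b_greater" the reverse.  Pooled-variance Student's t
    by default; ``welch=True`` uses the unequal-variance statistic with
    Welch–Satterthwaite degrees of freedom.
    """
    if direction not in ("a_greater", "b_greater"):
        raise ValueError("direction must be 'a_greater' or 'b_greater'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sem_a = math.sqrt(va / n_a)
    sem_b = math.sqrt(vb / n_b)

    degenerate = False
    if va == 0 and vb == 0 and ma == mb:
        t_stat, df, p = 0.0, float(n_a + n_b - 2), 0.5
        degenerate = True
    else:
        if welch:
            se2 = va / n_a + vb / n_b
            t_stat = (ma - mb) / math.sqrt(se2)
            df = se2**2 / (
                (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
            )
        else:
            sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
            t_stat = (ma - mb) / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
            df = float(n_a + n_b - 2)
        t_dir = t_stat if direction == "a_greater" else -t_stat
        p = float(t_dist.sf(t_dir, df))
    return GroupComparison(
        group_a=group_a, group_b=group_b,
        mean_a=float(ma), mean_b=float(mb),
        sem_a=float(sem_a), sem_b=float(sem_b),
        n_a=n_a, n_b=n_b,
        t_statistic=float(t_stat), df=float(df), p_one_tailed=float(p),
        significance_stars=significance_stars(p),
        direction=direction, welch=welch, degenerate=degenerate,
    )


def cell_summary(
    cell_id: str,
    density=None,
    events=None,
    zones=None,
    coloc=None,
    total_time_s: float | None = None,
) -> pd.DataFrame:
    """One summary row per cell: density, event counts by class, rates,
    zone fractions and colocalization, with NaN sentinels where a stage
    was not run or produced nothing."""
    row: dict[str, object] = {"cell_id": cell_id}
    row["density_per_um2"] = density.density_per_um2 if density else np.nan
    row["n_puncta"] = density.n_puncta if density else 0
    row["area_um2"] = density.area_um2 if density else np.nan

    events = events or []
    classes = ["docking", "undocking", "dock_and_undock", "visiting", "fusion"]
    for cls in classes:
        row[f"n_{cls}"] = sum(1 for e in events if e.event_class == cls)
    n_fusion = row["n_fusion"]
    if total_time_s and total_time_s > 0:
        row["fusion_events_per_min"] = n_fusion / (total_time_s / 60.0)
    else:
        row["fusion_events_per_min"] = np.nan
    durations = [e.release_duration_s for e in events
                 if e.release_duration_s is not None]
    row["mean_release_duration_s"] = (float(np.mean(durations))
                                      if durations else np.nan)

    row["fraction_peripheral"] = zones.fraction_peripheral if zones else np.nan
    row["fraction_non_peripheral"] = (zones.fraction_non_peripheral
                                      if zones else np.nan)
    row["percent_colocalized"] = (coloc.percent_colocalized
                                  if coloc else np.nan)
    return pd.DataFrame([row])
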