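"""Aggregation and statistical comparison of per-FOV metrics.

Metrics are first averaged within each field of view; FOVs (or wells, when
aggregated) are the replicates.  Group comparisons use one-way ANOVA with a
Tukey-Kramer post-hoc test (valid for unequal group sizes); associations use
the Pearson correlation with its two-sided p-value.  Dispersion is reported
as mean ± s.d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "aggregate",
    "anova_tukey",
    "pearson",
]

TIDY_COLUMNS = ["condition", "timepoint_h", "well", "fov", "metric", "value"]


@dataclass
class ComparisonResult:
    """Result of a group comparison or correlation."""

    anova_f: float | None = None
    df_between: int | None = None
    df_within: int | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None     # group1, group2, meandiff, p_adj, significant
    pearson_r: float | None = None
    pearson_p: float | None = None
    n: int | None = None
    alpha: float = 0.05
    summary: dict = field(default_factory=dict)  # group -> (mean, sd, n)


def aggregate(table: pd.DataFrame, level: str = "fov") -> pd.DataFrame:
    """Unweighted means of a tidy metric table at FOV or well level.

    The table must have the columns ``condition, timepoint_h, well, fov,
    metric, value`` with one value per (fov, metric).  Well-level aggregation
    averages each well's fields of view; the number of contributing values is
    recorded in an ``n`` column.  Missing FOV values simply reduce ``n``.
    """
    if table.empty:
        raise ValueError("empty metric table")
    missing = [c for c in TIDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table missing columns {missing}")
    if level == "fov":
        keys = ["condition", "timepoint_h", "well", "fov", "metric"]
    elif level == "well":
        keys = ["condition", "timepoint_h", "well", "metric"]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    grouped = (table.dropna(subset=["value"])
               .groupby(keys, as_index=False, sort=True)["value"]
               .agg(value="mean", n="count"))
    return grouped


@lru_cache(maxsize=64)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def anova_tukey(groups: list[np.ndarray] | dict[str, np.ndarray],
                alpha: float = 0.05, pvalues: bool = True) -> ComparisonResult:
    """One-way ANOVA with a Tukey-Kramer post-hoc test.

    ``groups`` is a list (auto-named ``g1..gk``) or dict of per-group value
    arrays, each with at least 2 values.  The Tukey-Kramer statistic for the
    pair (i, j) is ``|mi - mj| / sqrt(MSW/2 (1/ni + 1/nj))``, referred to the
    studentized-range distribution with k groups and N-k error degrees of
    freedom; the Kramer form is valid for unequal group sizes.  With
    ``pvalues=False`` adjusted p-values are skipped (significance flags still
    computed against the cached critical value), which makes large
    Monte-Carlo calibrations cheap.

    When every value is identical the degenerate result F = 0, p = 1 is
    returned; when groups are internally constant but differ, F is infinite
    and every differing pair is flagged.
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        data = [np.asarray(groups[k], float) for k in names]
    else:
        data = [np.asarray(g, float) for g in groups]
        names = [f"g{i + 1}" for i in range(len(data))]
    if len(data) < 2 or any(g.size < 2 for g in data):
        raise ValueError("need >= 2 groups with >= 2 values each")

    k = len(data)
    ns = np.array([g.size for g in data])
    n_tot = int(ns.sum())
    dfb, dfw = k - 1, n_tot - k
    summary = {nm: (float(g.mean()), float(g.std(ddof=1)), int(g.size))
               for nm, g in zip(names, data)}

    allv = np.concatenate(data)
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in data))
    grand = allv.mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, data)))
    if ssw == 0.0:
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
        pairs = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = data[j].mean() - data[i].mean()
                sig = ssb > 0 and diff != 0
                pairs.append((names[i], names[j], float(diff),
                              0.0 if sig else 1.0, bool(sig)))
        tukey = pd.DataFrame(pairs, columns=["group1", "group2", "meandiff",
                                             "p_adj", "significant"])
        return ComparisonResult(anova_f=f_stat, df_between=dfb, df_within=dfw,
                                anova_p=p, tukey=tukey, alpha=alpha,
                                summary=summary)

    f_stat, p = sps.f_oneway(*data)
    msw = ssw / dfw
    means = np.array([g.mean() for g in data])
    pair_idx = list(combinations(range(k), 2))
    diffs = np.array([means[j] - means[i] for i, j in pair_idx])
    ses = np.array([math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                    for i, j in pair_idx])
    q_stats = np.abs(diffs) / ses
    reject = q_stats > _q_crit(alpha, k, dfw)
    p_adj = (sps.studentized_range.sf(q_stats, k, dfw) if pvalues
             else np.full(q_stats.size, np.nan))
    tukey = pd.DataFrame({
        "group1": [names[i] for i, _ in pair_idx],
        "group2": [names[j] for _, j in pair_idx],
        "meandiff": diffs,
        "p_adj": np.clip(p_adj, 0.0, 1.0),
        "significant": reject,
    })
    return ComparisonResult(anova_f=float(f_stat), df_between=dfb,
                            df_within=dfw, anova_p=float(p), tukey=tukey,
                            alpha=alpha, summary=summary)


def pearson(x: np.ndarray, y: np.ndarray) -> ComparisonResult:
    """Pearson correlation coefficient with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return ComparisonResult(pearson_r=float(r), pearson_p=float(p), n=int(x.size))
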