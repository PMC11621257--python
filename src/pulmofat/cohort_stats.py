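"""Cohort statistics: normality assessment, Kruskal–Wallis, Dunn post hoc.

The battery mirrors the standard nonparametric workflow for skewed
volumetric biomarkers: a D'Agostino–Pearson K² normality check per group,
a Kruskal–Wallis omnibus test across groups, Dunn's multiple-comparison
post hoc with a Bonferroni-style adjustment, and median/IQR descriptives.
The nonparametric path is always run regardless of the normality outcome;
the normality results are reported for transparency.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsPreconditionError

__all__ = [
    "TestReport",
    "dagostino_pearson",
    "kruskal_wallis",
    "dunn_posthoc",
    "describe",
    "run_battery",
]


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.isfinite(arr).all():
        raise StatisticsPreconditionError("metric values must be finite")
    return arr


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test.

    K² combines the standardized skewness and kurtosis transforms and is
    referred to a chi-square distribution with 2 df.  Undefined below n = 8
    (the skewness transform breaks down); a UserWarning-free but weak
    approximation for 8 <= n < 20 is the caller's concern.
    """
    arr = _clean(values)
    if arr.size < 8:
        raise StatisticsPreconditionError(
            f"D'Agostino–Pearson test requires n >= 8, got n = {arr.size}"
        )
    k2, p = stats.normaltest(arr)
    return float(k2), float(p)


def kruskal_wallis(groups) -> tuple[float, float, int]:
    """Kruskal–Wallis rank test with tie correction.

    Returns (H, p, df) with df = k - 1 and p from the chi-square reference
    distribution.  The all-ties degenerate case is defined as H = 0, p = 1.
    """
    arrays = [_clean(g) for g in groups]
    if len(arrays) < 2:
        raise StatisticsPreconditionError("Kruskal–Wallis requires at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise StatisticsPreconditionError("Kruskal–Wallis groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise StatisticsPreconditionError("Kruskal–Wallis requires total n >= 3")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # every observation tied: no evidence, H = 0
        return 0.0, 1.0, df
    h, p = stats.kruskal(*arrays)
    return float(h), float(p), df


def _pooled_ranks(arrays: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Mid-ranks of each group in the pooled sample and the tie term.

    The tie term sum(t^3 - t) over tied value groups enters Dunn's variance
    as its standard correction.
    """
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for a in arrays:
        out.append(ranks[start : start + a.size])
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return out, tie_sum


def dunn_posthoc(groups, labels=None, adjustment: str = "bonferroni_style") -> pd.DataFrame:
    """Dunn's multiple-comparison test on pooled ranks.

    For groups i, j the statistic is

        z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )

    with T = sum(t^3 - t) the tie correction.  Two-sided p-values from the
    standard normal; adjusted p = min(1, p * k(k-1)/2) (Bonferroni-style,
    the behavior of the common "Dunn's multiple comparison" implementations).
    Degenerate all-tied data yields z = 0, p = 1.
    """
    if adjustment != "bonferroni_style":
        raise ValueError(f"unknown adjustment {adjustment!r}")
    arrays = [_clean(g) for g in groups]
    if len(arrays) < 2:
        raise StatisticsPreconditionError("Dunn post hoc requires at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise StatisticsPreconditionError("Dunn post hoc groups must be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    ranks, tie_sum = _pooled_ranks(arrays)
    n_total = sum(a.size for a in arrays)
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    n_comp = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se2 = var_term * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        diff = ranks[i].mean() - ranks[j].mean()
        z = 0.0 if se2 <= 0 else diff / math.sqrt(se2)
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_comp),
            }
        )
    return pd.DataFrame(rows)


def describe(values) -> tuple[float, float, float, float]:
    """Median and quartiles by linear interpolation between order statistics.

    Returns (median, q1, q3, iqr_width); both the (q1, q3) range and the
    width q3 - q1 are conventional reporting styles for skewed biomarkers.
    """
    arr = _clean(values)
    if arr.size == 0:
        raise StatisticsPreconditionError("describe requires at least one value")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3), float(q3 - q1)


@dataclass
class TestReport:
    """Full battery output for one metric across cohort groups."""

    metric: str
    alpha: float
    normality: dict[str, dict]  # group -> {k2, p} or {error}
    omnibus: dict  # {H, p, df}
    posthoc: pd.DataFrame
    descriptives: pd.DataFrame
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "alpha": self.alpha,
            "normality": self.normality,
            "omnibus": self.omnibus,
            "posthoc": self.posthoc.to_dict(orient="records"),
            "descriptives": self.descriptives.to_dict(orient="records"),
            "significant_pairs": [list(p) for p in self.significant_pairs],
        }


def run_battery(
    table: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    group_col: str = "group",
) -> TestReport:
    """Run the full statistics sequence on one metric of a cohort table.

    Per-group normality (where n allows), Kruskal–Wallis omnibus, Dunn post
    hoc, and median/IQR descriptives; pairs with adjusted p below ``alpha``
    are flagged.
    """
    if metric not in table.columns:
        raise StatisticsPreconditionError(
            f"metric column {metric!r} not in table (have {sorted(table.columns)})"
        )
    if group_col not in table.columns:
        raise StatisticsPreconditionError(f"group column {group_col!r} not in table")
    groups = {str(g): _clean(sub[metric]) for g, sub in table.groupby(group_col, sort=False)}
    if len(groups) < 2 or any(a.size == 0 for a in groups.values()):
        raise StatisticsPreconditionError("battery requires >= 2 groups with >= 1 observation each")

    normality: dict[str, dict] = {}
    for name, vals in groups.items():
        try:
            k2, p = dagostino_pearson(vals)
            entry: dict = {"k2": k2, "p": p}
            if vals.size < 20:
                entry["warning"] = f"n = {vals.size} < 20: chi-square approximation is weak"
            normality[name] = entry
        except StatisticsPreconditionError as exc:
            normality[name] = {"error": str(exc)}

    labels = list(groups)
    h, p, df = kruskal_wallis(list(groups.values()))
    posthoc = dunn_posthoc(list(groups.values()), labels=labels)
    desc_rows = []
    for name, vals in groups.items():
        med, q1, q3, width = describe(vals)
        desc_rows.append(
            {"group": name, "n": vals.size, "median": med, "q1": q1, "q3": q3, "iqr_width": width}
        )
    sig = [
        (r.group_a, r.group_b)
        for r in posthoc.itertuples()
        if r.p_adjusted < alpha
    ]
    return TestReport(
        metric=metric,
        alpha=alpha,
        normality=normality,
        omnibus={"H": h, "p": p, "df": df},
        posthoc=posthoc,
        descriptives=pd.DataFrame(desc_rows),
        significant_pairs=sig,
    )
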