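"""Condition-level aggregation and statistical comparison.

Wells are the replicate unit: per-field metrics are averaged into one value
per well per day, then conditions are compared day-by-day with a one-way
ANOVA followed by Bonferroni-adjusted pairwise comparisons.  The pairwise
tests use the pooled within-group mean square from the ANOVA (the
conventional post-hoc, as computed by common statistics packages), with raw
p-values multiplied by the number of pairs and capped at 1.

Timing of differentiation is summarised by the interpolated day at which the
mean fusion index first reaches a given fraction of its course maximum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientReplicationError,
    ReconciliationError,
    ValidationError,
)

_METRIC_COLUMNS = {"fusion_index": "fusion_index_pct", "nuclei_count": "total_nuclei"}


@dataclass
class TimeCourse:
    """Per-condition time course of well-level replicate values.

    ``fusion_index[day]`` and ``nuclei_count[day]`` are arrays with one entry
    per well (fields pooled by mean).  Days listed in the manifest but absent
    from the results are recorded in ``missing_days``, never imputed.
    """

    condition: str
    days: list[int]
    fusion_index: dict[int, np.ndarray]
    nuclei_count: dict[int, np.ndarray]
    missing_days: list[int] = field(default_factory=list)

    def mean_series(self, metric: str = "fusion_index") -> pd.Series:
        values = getattr(self, metric)
        return pd.Series({d: float(np.mean(values[d])) for d in self.days})


def aggregate(results: pd.DataFrame, manifest: dict) -> list[TimeCourse]:
    """Aggregate per-scene results into one :class:`TimeCourse` per condition.

    Every result row must correspond to a manifest scene; orphans raise a
    :class:`ReconciliationError` listing them.  Field-level values are
    averaged into well-level replicates.
    """
    keys = {"condition", "well_id", "day", "field_index"}
    missing_cols = keys - set(results.columns)
    if missing_cols:
        raise ReconciliationError(f"results table lacks columns {sorted(missing_cols)}")

    manifest_keys = {
        (s["condition"], s["well_id"], int(s["day"]), int(s["field_index"]))
        for s in manifest["scenes"]
    }
    orphans = [
        tuple(row)
        for row in results[["condition", "well_id", "day", "field_index"]].itertuples(index=False)
        if (row.condition, row.well_id, int(row.day), int(row.field_index)) not in manifest_keys
    ]
    if orphans:
        raise ReconciliationError(f"results not present in manifest: {orphans}")

    well_level = (
        results.groupby(["condition", "well_id", "day"], as_index=False)[
            ["fusion_index_pct", "total_nuclei"]
        ].mean()
    )

    courses = []
    for condition in manifest.get("conditions") or sorted(well_level["condition"].unique()):
        sub = well_level[well_level["condition"] == condition]
        manifest_days = sorted(
            {int(s["day"]) for s in manifest["scenes"] if s["condition"] == condition}
        )
        present_days = sorted(sub["day"].unique())
        fusion, nuclei = {}, {}
        for d in present_days:
            day_rows = sub[sub["day"] == d].sort_values("well_id")
            fusion[int(d)] = day_rows["fusion_index_pct"].to_numpy(dtype=float)
            nuclei[int(d)] = day_rows["total_nuclei"].to_numpy(dtype=float)
        courses.append(
            TimeCourse(
                condition=condition,
                days=[int(d) for d in present_days],
                fusion_index=fusion,
                nuclei_count=nuclei,
                missing_days=[d for d in manifest_days if d not in set(map(int, present_days))],
            )
        )
    return courses


@dataclass
class ComparisonResult:
    """One-way ANOVA across conditions plus Bonferroni-adjusted pairwise tests."""

    day: int
    metric: str
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # columns: condition_a, condition_b, mean_a, mean_b,
    #                                   t_stat, p_raw, p_adj, significant


def compare_conditions(
    timecourses: list[TimeCourse],
    day: int,
    metric: str = "fusion_index",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare conditions on one day: ANOVA F/p and all pairwise tests.

    Degenerate inputs (all replicate values identical across every group)
    yield p = 1 with no significance flags rather than a NaN.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValidationError(f"metric must be one of {sorted(_METRIC_COLUMNS)}, got {metric!r}")
    groups, names = [], []
    for tc in timecourses:
        values = getattr(tc, metric).get(day)
        if values is None:
            continue
        names.append(tc.condition)
        groups.append(np.asarray(values, dtype=float))
    if len(groups) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 conditions with data on day {day}, found {len(groups)}"
        )
    if any(len(g) < 2 for g in groups):
        raise InsufficientReplicationError(
            f"every condition needs >= 2 replicates on day {day}"
        )

    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        f_stat, p_value = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_value = float(stats.f.sf(f_stat, df_b, df_w))

    mse = ss_within / df_w if df_w > 0 else 0.0
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        dm = a.mean() - b.mean()
        if mse > 0:
            t_stat = dm / np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            p_raw = float(2 * stats.t.sf(abs(t_stat), df_w))
        else:
            t_stat = 0.0 if dm == 0 else float("inf") * np.sign(dm)
            p_raw = 1.0 if dm == 0 else 0.0
        p_adj = min(1.0, p_raw * len(pairs))
        rows.append(
            {
                "condition_a": names[i],
                "condition_b": names[j],
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t_stat": float(t_stat),
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    return ComparisonResult(
        day=day, metric=metric, f_stat=float(f_stat), p_value=p_value, pairwise=pd.DataFrame(rows)
    )


def time_to_fraction_max(
    tc: TimeCourse, fraction: float = 0.9, metric: str = "fusion_index"
) -> float:
    """Earliest (linearly interpolated) day at which the mean time course
    reaches ``fraction`` of its maximum over the course.

    The maximum is attained within the course, so the threshold is always
    reached — at the argmax day at the latest.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    series = tc.mean_series(metric)
    if series.empty:
        raise ValidationError(f"time course for {tc.condition!r} is empty")
    days = np.asarray(series.index, dtype=float)
    means = series.to_numpy(dtype=float)
    target = fraction * means.max()
    for i, (d, m) in enumerate(zip(days, means)):
        if m >= target:
            if i == 0 or means[i] == means[i - 1]:
                return float(d)
            frac = (target - means[i - 1]) / (means[i] - means[i - 1])
            return float(days[i - 1] + frac * (d - days[i - 1]))
    return float(days[-1])  # unreachable: max is attained in the course


def timecourse_table(timecourses: list[TimeCourse]) -> pd.DataFrame:
    """Long-format table of well-level replicates, one row per
    (condition, day, replicate)."""
    rows = []
    for tc in timecourses:
        for d in tc.days:
            for rep, (fi, nc) in enumerate(zip(tc.fusion_index[d], tc.nuclei_count[d])):
                rows.append(
                    {
                        "condition": tc.condition,
                        "day": d,
                        "replicate": rep,
                        "fusion_index_pct": fi,
                        "total_nuclei": nc,
                    }
                )
    return pd.DataFrame(rows)
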