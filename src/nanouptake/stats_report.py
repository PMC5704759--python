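"""Descriptive statistics and group comparisons for uptake tables.

Mirrors the study's reporting style: mean +/- one standard deviation,
t-based 95% confidence intervals, and two-sample Student's t-tests at
alpha = 5% (classical equal-variance form; Welch available via a flag).
Single- versus co-exposure tables are compared per channel and timepoint
as percent differences in mean load together with the t-test outcome.
No multiple-testing correction is applied; raw p values are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["GroupSummary", "ComparisonResult", "summarize", "ttest", "compare_exposures"]

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, str]
    t_statistic: float
    p_value: float
    significant: bool
    fold_difference: float


def summarize(values, group: str = "") -> GroupSummary:
    """Mean, sample SD (n-1) and t-based 95% CI of one group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("empty group")
    mean = float(v.mean())
    if v.size == 1:
        return GroupSummary(group, 1, mean, 0.0, (mean, mean))
    sd = float(v.std(ddof=1))
    half = sps.t.ppf(1 - ALPHA / 2, v.size - 1) * sd / np.sqrt(v.size)
    return GroupSummary(group, int(v.size), mean, sd, (mean - half, mean + half))


def ttest(a, b, *, welch: bool = False, groups: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Two-sided two-sample Student's t-test at alpha = 5%.

    Equal-variance by default (the classical Student form); set
    ``welch=True`` for unequal variances.  Identical groups with zero
    pooled variance are reported as t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    mean_b = b.mean()
    fold = float(a.mean() / mean_b) if mean_b != 0 else float("nan")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("zero pooled variance with equal means: p = 1 by convention")
            return ComparisonResult(groups, 0.0, 1.0, False, fold)
        return ComparisonResult(groups, float("inf"), 0.0, True, fold)
    t_stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(groups, float(t_stat), float(p), bool(p < ALPHA), fold)


def compare_exposures(
    single: pd.DataFrame,
    co: pd.DataFrame,
    value: str = "load",
    by: tuple[str, ...] = ("channel", "time"),
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Per channel/timepoint co- vs single-exposure comparison.

    Both tables are per-cell records as produced by
    :func:`nanouptake.imaging.quantify_stack`.  For every group key
    present in either table the percent difference in mean ``value``,
    100 * (mean_co - mean_single) / mean_single, is computed together
    with the Student's t-test.  Missing matched groups raise with the
    list of gaps.
    """
    for df, name in ((single, "single"), (co, "co")):
        missing = [c for c in (*by, value) if c not in df.columns]
        if missing:
            raise StatsError(f"{name} table lacks columns {missing}")
    keys = [k for k in by if single[k].notna().any() or co[k].notna().any()]
    g_single = dict(tuple(single.groupby(list(keys))))
    g_co = dict(tuple(co.groupby(list(keys))))
    gaps = sorted(set(g_single) ^ set(g_co))
    if gaps:
        raise StatsError(f"unmatched groups between tables: {gaps}")

    rows = []
    for key in sorted(g_single):
        vs = g_single[key][value].to_numpy(dtype=float)
        vc = g_co[key][value].to_numpy(dtype=float)
        mean_s = vs.mean()
        pct = 100.0 * (vc.mean() - mean_s) / mean_s if mean_s != 0 else float("nan")
        res = ttest(vc, vs, welch=welch, groups=("co", "single"))
        key_t = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(keys, key_t)),
                "n_single": len(vs),
                "n_co": len(vc),
                "mean_single": mean_s,
                "mean_co": vc.mean(),
                "percent_difference": pct,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def summary_report(comparisons: pd.DataFrame) -> str:
    """Markdown rendering of a comparison table with significance flags."""
    lines = ["| " + " | ".join(comparisons.columns) + " |"]
    lines.append("|" + "---|" * len(comparisons.columns))
    for _, row in comparisons.iterrows():
        cells = [
            f"{v:.3g}" if isinstance(v, (int, float, np.floating)) and not isinstance(v, bool) else str(v)
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
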