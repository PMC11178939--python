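"""Group summaries and significance testing for per-flagellum metrics.

Groups are compared with an unpaired two-tailed t test (Welch's
unequal-variance form by default; a flag restores the pooled-variance
Student form) and p-values across the explicitly listed comparisons are
adjusted with the Holm–Bonferroni step-down procedure; significance is
called at the configured alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float | None  # sample SD / sqrt(n); undefined at n = 1


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    se_a: float | None
    se_b: float | None
    t_stat: float
    p_raw: float
    p_adjusted: float
    significant: bool


def summarize(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean, SE (n-1 denominator SD / sqrt(n)) and n per group."""
    out = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise InputError(f"group {name!r} is empty")
        se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
        out.append(GroupSummary(group=str(name), n=int(v.size), mean=float(v.mean()), se=se))
    return out


def t_test_unpaired(a, b, *, equal_var: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed t test; Welch by default.

    Returns (t_stat, p_raw). Two identical constant groups give (0, 1) by
    convention; constant groups with different means give (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment, order-preserving.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the sorted
    p-values, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("no p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum((m - np.arange(m)) * p[order], 1.0)
    stepped = np.maximum.accumulate(scaled)
    adjusted = np.empty(m)
    adjusted[order] = stepped
    return adjusted


def compare_groups(
    data: pd.DataFrame,
    metric: str,
    comparisons: Sequence[tuple[str, str]],
    *,
    alpha: float = 0.05,
    equal_var: bool = False,
    group_column: str = "group",
) -> list[GroupComparison]:
    """Welch (or Student) tests per listed pair, Holm–Bonferroni across them.

    The multiplicity family is exactly the listed comparisons. Rows whose
    metric is undefined (NaN) are excluded from that group's n.
    """
    if metric not in data.columns:
        raise InputError(f"metric {metric!r} not in results")
    if group_column not in data.columns:
        raise InputError(f"column {group_column!r} not in results")
    if not comparisons:
        raise InputError("no comparisons listed")
    values: dict[str, np.ndarray] = {}
    for g, sub in data.groupby(group_column, sort=False):
        v = sub[metric].to_numpy(dtype=float)
        values[str(g)] = v[np.isfinite(v)]

    p_raw, stats_rows = [], []
    for ga, gb in comparisons:
        for g in (ga, gb):
            if g not in values:
                raise InputError(f"unknown group label {g!r}")
            if values[g].size < 2:
                raise InputError(f"group {g!r} has n < 2 for metric {metric!r}")
        a, b = values[ga], values[gb]
        t, p = t_test_unpaired(a, b, equal_var=equal_var)
        p_raw.append(max(p, np.finfo(float).tiny))  # p=0 only at exact separation
        stats_rows.append((ga, gb, a, b, t))
    p_adj = holm_bonferroni(p_raw)

    out = []
    for (ga, gb, a, b, t), praw, padj in zip(stats_rows, p_raw, p_adj):
        se_a = float(np.std(a, ddof=1) / np.sqrt(a.size)) if a.size > 1 else None
        se_b = float(np.std(b, ddof=1) / np.sqrt(b.size)) if b.size > 1 else None
        out.append(
            GroupComparison(
                group_a=ga,
                group_b=gb,
                n_a=int(a.size),
                n_b=int(b.size),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                se_a=se_a,
                se_b=se_b,
                t_stat=float(t),
                p_raw=float(praw),
                p_adjusted=float(padj),
                significant=bool(padj < alpha),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
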