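"""Group aggregation, rank tests and box-and-whisker summaries of ratios.

Per-section coverage ratios are grouped by marker and age and compared with
a two-sided Mann-Whitney U test (exact null distribution for small groups,
tie-corrected normal approximation otherwise; Welch's t is available behind
a flag). Box summaries use Tukey hinge quartiles (median-inclusive halves)
so that the "disjoint boxes" reading — three quarters of one group above
three quarters of the other — matches the plotted boxes. Raw p-values are
reported without multiple-testing correction (two planned comparisons), and
sections are treated as independent replicates; an animal-id column can be
carried through for hierarchical reanalysis elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "tukey_hinges",
    "compare_groups",
    "boxes_disjoint",
    "summarize_groups",
    "compare_table",
    "plot_boxes",
]

# full tied-case enumeration is used up to this many label arrangements
_ENUMERATION_LIMIT = 200_000


def tukey_hinges(values: Sequence[float]) -> Tuple[float, float]:
    """(Q1, Q3) as medians of the lower/upper halves, median included in
    both halves when n is odd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("hinges need at least 2 values")
    lower = x[: (n + 1) // 2]
    upper = x[n // 2 :]
    return float(np.median(lower)), float(np.median(upper))


@dataclass
class GroupSummary:
    """Five-number summary (plus mean) of one marker x age group."""

    label: str
    n: int
    median: float
    mean: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    values: np.ndarray

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        if x.size < 2:
            raise ValueError("a group summary needs at least 2 values")
        q1, q3 = tukey_hinges(x)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        return cls(
            label=label,
            n=int(x.size),
            median=float(np.median(x)),
            mean=float(x.mean()),
            q1=q1,
            q3=q3,
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            values=x,
        )


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def _exact_p_enumeration(combined: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p over all assignments of the observed values to
    groups, using midranks (valid with ties; null symmetric about n_a*n_b/2)."""
    ranks = sps.rankdata(combined)
    n = len(combined)
    n_b = n - n_a
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        u = _u_statistic(ranks[list(idx)], n_a)
        if abs(u - mu) >= dev - 1e-9:
            count += 1
        total += 1
    return count / total


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    *,
    method: str = "mannwhitney",
) -> Tuple[float, float]:
    """Two-sided comparison of two groups of per-section ratios.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of the first
    group. Without ties the exact null distribution is used whenever both
    groups have at most 20 values; with ties, the exact p is obtained by
    full enumeration while the number of group assignments is small, and a
    tie-corrected normal approximation (with continuity correction)
    otherwise. ``method="welch"`` runs Welch's t test instead and returns
    ``(t, p)``. Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if method == "welch":
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if method != "mannwhitney":
        raise ValueError(f"unknown method {method!r}")

    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u_a = _u_statistic(ranks[: a.size], a.size)
    if np.ptp(combined) == 0:
        warnings.warn("all values tied across both groups; p = 1", UserWarning)
        return u_a, 1.0

    has_ties = np.unique(combined).size < combined.size
    if not has_ties and max(a.size, b.size) <= 20:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if has_ties and math.comb(a.size + b.size, a.size) <= _ENUMERATION_LIMIT:
        return u_a, _exact_p_enumeration(combined, a.size, u_a)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def boxes_disjoint(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff the boxes do not overlap: the lower hinge of the
    higher-median group exceeds the upper hinge of the other.

    When true, three quarters of one group's values lie above three
    quarters of the other's. Quartiles are Tukey hinges.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 4 or b.size < 4:
        raise ValueError("each group needs at least 4 values")
    if np.median(a) >= np.median(b):
        high, low = a, b
    else:
        high, low = b, a
    q1_high, _ = tukey_hinges(high)
    _, q3_low = tukey_hinges(low)
    return bool(q1_high > q3_low)


def summarize_groups(
    records: pd.DataFrame,
    group_by: Sequence[str] = ("channel", "age"),
    value: str = "ratio",
) -> pd.DataFrame:
    """One summary row per group from a per-section records table."""
    rows: List[Dict[str, object]] = []
    for key, grp in records.groupby(list(group_by), sort=True):
        key_t = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key_t)
        s = GroupSummary.from_values(label, grp[value].to_numpy())
        row: Dict[str, object] = dict(zip(group_by, key_t))
        row.update(
            n=s.n, median=s.median, mean=s.mean, q1=s.q1, q3=s.q3,
            whisker_low=s.whisker_low, whisker_high=s.whisker_high,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_table(
    groups: Mapping[str, Sequence[float]], *, method: str = "mannwhitney"
) -> pd.DataFrame:
    """All pairwise group comparisons (raw p-values, no correction)."""
    rows = []
    names = list(groups)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            stat, p = compare_groups(groups[ga], groups[gb], method=method)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "statistic": stat,
                    "p_value": p,
                    "boxes_disjoint": (
                        boxes_disjoint(groups[ga], groups[gb])
                        if len(groups[ga]) >= 4 and len(groups[gb]) >= 4
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def plot_boxes(
    groups: Mapping[str, Sequence[float]],
    *,
    ylabel: str = "coverage ratio (module/matrix)",
    path: Optional[str] = None,
):
    """Box-and-whisker figure with median lines and mean markers ('x').

    Boxes are drawn from the same Tukey hinges used by
    :func:`boxes_disjoint`, via precomputed stats, so figure and test agree.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = []
    for label, values in groups.items():
        s = GroupSummary.from_values(label, values)
        fliers = s.values[(s.values < s.whisker_low) | (s.values > s.whisker_high)]
        stats.append(
            {
                "label": s.label,
                "med": s.median,
                "mean": s.mean,
                "q1": s.q1,
                "q3": s.q3,
                "whislo": s.whisker_low,
                "whishi": s.whisker_high,
                "fliers": fliers,
            }
        )
    fig, ax = plt.subplots(figsize=(1.6 * len(stats) + 1.5, 4))
    ax.bxp(stats, showmeans=True, meanprops={"marker": "x"})
    ax.axhline(1.0, color="0.6", linestyle=":", linewidth=1)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig, ax
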