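"""Nonparametric group comparison and reporting for activity tables.

The workflow follows common practice for small-N embryo reporter data:
normality is screened per group with Shapiro-Wilk, outliers are flagged by
the 1.5 x IQR rule but never dropped (dropping would eliminate whole small
groups), multi-group differences are tested with Kruskal-Wallis followed by
Dunn's pairwise comparisons under Bonferroni correction, two-group
differences with the Mann-Whitney U test, and results are reported as swarm
plots with red median bars and significance stars.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MeasurementTable",
    "ComparisonResult",
    "normality_screen",
    "iqr_outlier_flags",
    "kruskal_wallis",
    "dunn_bonferroni",
    "mann_whitney",
    "compare_groups",
    "star_annotation",
    "swarm_report",
    "STAR_SCHEMES",
]


class StatsError(ValueError):
    """Invalid input to a statistical operation."""


# Star thresholds are strict (<). The default scheme is the methods-text
# scheme; the 'figure' preset is the coarser legend scheme some figures use.
STAR_SCHEMES: dict[str, list[tuple[float, str]]] = {
    "methods": [(0.0001, "****"), (0.0005, "***"), (0.005, "**"), (0.05, "*")],
    "figure": [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")],
}


@dataclass
class MeasurementTable:
    """Per-embryo activity measurements grouped for comparison."""

    data: pd.DataFrame  # columns: embryo_id, group, relative_activity
    group_order: list[str] | None = None

    def __post_init__(self) -> None:
        required = {"embryo_id", "group", "relative_activity"}
        missing = required - set(self.data.columns)
        if missing:
            raise StatsError(f"measurement table missing columns {missing}")
        vals = self.data["relative_activity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise StatsError("relative_activity must be finite and >= 0")
        present = list(dict.fromkeys(self.data["group"]))
        if self.group_order is None:
            self.group_order = present
        else:
            unknown = set(self.group_order) - set(present)
            if unknown:
                raise StatsError(f"group_order names absent groups {unknown}")

    @classmethod
    def from_records(cls, records, group_order=None) -> "MeasurementTable":
        """Build from ActivityRecord objects, skipping excluded embryos."""
        rows = [r.to_row() for r in records if not r.excluded]
        return cls(pd.DataFrame(rows)[["embryo_id", "group",
                                       "relative_activity"]], group_order)

    @classmethod
    def from_csv(cls, path, group_order=None) -> "MeasurementTable":
        return cls(pd.read_csv(path), group_order)

    @property
    def groups(self) -> list[str]:
        return list(self.group_order)

    def values(self, group: str) -> np.ndarray:
        sel = self.data.loc[self.data["group"] == group, "relative_activity"]
        return sel.to_numpy(dtype=float)

    def by_group(self) -> dict[str, np.ndarray]:
        return {g: self.values(g) for g in self.groups}


@dataclass
class ComparisonResult:
    """Outcome of a group-comparison test.

    ``pairwise`` maps (groupA, groupB) to Bonferroni-corrected p (raw p in
    ``pairwise_raw``); ``stars`` annotates each comparison (or the omnibus
    test for two-group results).
    """

    test_name: str
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] | None = None
    pairwise_raw: dict[tuple[str, str], float] | None = None
    stars: dict = field(default_factory=dict)
    degenerate: bool = False
    group_n: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        pair_key = lambda d: ({f"{a} vs {b}": p for (a, b), p in d.items()}
                              if d else None)
        return {
            "test": self.test_name, "statistic": self.statistic,
            "p_value": self.p_value, "degenerate": self.degenerate,
            "pairwise_corrected": pair_key(self.pairwise),
            "pairwise_raw": pair_key(self.pairwise_raw),
            "stars": {(f"{k[0]} vs {k[1]}" if isinstance(k, tuple) else k): v
                      for k, v in self.stars.items()},
            "group_n": self.group_n,
        }


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def normality_screen(table: MeasurementTable) -> dict[str, dict]:
    """Shapiro-Wilk W and p per group; groups with n < 3 or constant values
    are reported not-testable rather than raising."""
    out: dict[str, dict] = {}
    for group in table.groups:
        vals = table.values(group)
        entry: dict = {"n": int(vals.size)}
        if vals.size < 3 or np.ptp(vals) == 0:
            entry.update(testable=False, W=math.nan, p=math.nan)
        else:
            res = sps.shapiro(vals)
            entry.update(testable=True, W=float(res.statistic),
                         p=float(res.pvalue))
        out[group] = entry
    return out


def iqr_outlier_flags(values: Sequence[float]) -> np.ndarray | None:
    """Flag values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR]; nothing is removed.

    Quartiles use linear interpolation (the type-7 convention). Returns a
    boolean array, or None when n < 4 (the rule is not applicable).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        return None
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def kruskal_wallis(table: MeasurementTable,
                   star_scheme: str = "methods") -> ComparisonResult:
    """Kruskal-Wallis H test across >= 3 groups (tie-corrected, chi-squared
    approximation with k-1 df). All-identical data is degenerate: H = 0,
    p = 1."""
    groups = table.by_group()
    if len(groups) < 3:
        raise StatsError("Kruskal-Wallis needs >= 3 groups; use mann_whitney "
                         "for two")
    samples = list(groups.values())
    pooled = np.concatenate(samples)
    group_n = {g: int(v.size) for g, v in groups.items()}
    if np.ptp(pooled) == 0:
        return ComparisonResult("kruskal-wallis", 0.0, 1.0, degenerate=True,
                                stars={"omnibus": "ns"}, group_n=group_n)
    h, p = sps.kruskal(*samples)
    return ComparisonResult("kruskal-wallis", float(h), float(p),
                            stars={"omnibus": star_annotation(p, star_scheme)},
                            group_n=group_n)


def dunn_bonferroni(table: MeasurementTable,
                    comparisons: Sequence[tuple[str, str]] | None = None,
                    star_scheme: str = "methods") -> ComparisonResult:
    """Dunn's post hoc pairwise comparisons with Bonferroni correction.

    z statistics use pooled mean ranks with the tie correction
    sum(t^3 - t) / (12 (N - 1)); raw two-sided p comes from the standard
    normal and the Bonferroni multiplier is the number of comparisons
    actually performed (all pairs by default), clamped at 1.
    """
    groups = table.by_group()
    for g, v in groups.items():
        if v.size == 0:
            raise StatsError(f"group {g!r} is empty")
    if comparisons is None:
        comparisons = list(itertools.combinations(table.groups, 2))
    else:
        for a, b in comparisons:
            if a not in groups or b not in groups:
                raise StatsError(f"unknown group in comparison ({a}, {b})")
    m = len(comparisons)

    pooled = np.concatenate([groups[g] for g in table.groups])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    offsets = {}
    pos = 0
    for g in table.groups:
        offsets[g] = (pos, pos + groups[g].size)
        pos += groups[g].size
    mean_rank = {g: ranks[s:e].mean() for g, (s, e) in offsets.items()}

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()
                / (12 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12 - tie_term

    raw: dict[tuple[str, str], float] = {}
    corrected: dict[tuple[str, str], float] = {}
    stars: dict[tuple[str, str], str] = {}
    max_z = 0.0
    for a, b in comparisons:
        na, nb = groups[a].size, groups[b].size
        se = math.sqrt(var_base * (1 / na + 1 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2 * sps.norm.sf(abs(z))
        raw[(a, b)] = float(p_raw)
        corrected[(a, b)] = float(min(1.0, m * p_raw))
        stars[(a, b)] = star_annotation(corrected[(a, b)], star_scheme)
        max_z = max(max_z, abs(z))

    return ComparisonResult("dunn-bonferroni", max_z,
                            min(corrected.values()) if corrected else 1.0,
                            pairwise=corrected, pairwise_raw=raw, stars=stars,
                            group_n={g: int(v.size) for g, v in groups.items()})


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group assignments.

    Handles ties: the U distribution is built over every C(n1+n2, n1) way of
    assigning the pooled (possibly tied) values to group A, and the p-value
    is the probability of a U at least as far from the null mean n1*n2/2 as
    observed.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 star_scheme: str = "methods",
                 exact_max_n: int = 8) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration (tie-safe) when both groups have <= ``exact_max_n``
    observations; otherwise the tie-corrected normal approximation with
    continuity correction. The statistic reported is U for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    if max(a.size, b.size) <= exact_max_n:
        u, p = _mann_whitney_exact(a, b)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    result = ComparisonResult("mann-whitney", u, min(1.0, float(p)),
                              stars={"omnibus": star_annotation(min(1.0, p),
                                                                star_scheme)},
                              group_n={"A": int(a.size), "B": int(b.size)})
    result.stars["method"] = method
    return result


def compare_groups(table: MeasurementTable,
                   comparisons: Sequence[tuple[str, str]] | None = None,
                   star_scheme: str = "methods"
                   ) -> dict[str, ComparisonResult]:
    """Route a table to the appropriate test(s).

    Two groups: Mann-Whitney U. Three or more: Kruskal-Wallis omnibus plus
    Dunn/Bonferroni pairwise comparisons.
    """
    groups = table.groups
    if len(groups) < 2:
        raise StatsError("need >= 2 groups to compare")
    if len(groups) == 2:
        res = mann_whitney(table.values(groups[0]), table.values(groups[1]),
                           star_scheme)
        res.pairwise = {(groups[0], groups[1]): res.p_value}
        res.pairwise_raw = dict(res.pairwise)
        res.stars[(groups[0], groups[1])] = res.stars["omnibus"]
        return {"omnibus": res}
    return {
        "omnibus": kruskal_wallis(table, star_scheme),
        "posthoc": dunn_bonferroni(table, comparisons, star_scheme),
    }


def star_annotation(p: float, scheme: str = "methods") -> str:
    """Map a p-value to significance stars with strict thresholds.

    Default scheme: **** p < 0.0001, *** p < 0.0005, ** p < 0.005,
    * p < 0.05, otherwise 'ns'. The 'figure' preset uses 0.001 / 0.01 for
    ***/**.
    """
    if not 0 <= p <= 1:
        raise StatsError(f"p-value must be in [0, 1], got {p}")
    for threshold, stars in STAR_SCHEMES[scheme]:
        if p < threshold:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def group_summary(table: MeasurementTable) -> pd.DataFrame:
    """Per-group n, median, quartiles, IQR and outlier count."""
    rows = []
    for g in table.groups:
        vals = table.values(g)
        q1, med, q3 = (np.quantile(vals, [0.25, 0.5, 0.75])
                       if vals.size else (math.nan,) * 3)
        flags = iqr_outlier_flags(vals)
        rows.append({"group": g, "n": int(vals.size), "median": float(med),
                     "q1": float(q1), "q3": float(q3),
                     "iqr": float(q3 - q1),
                     "n_outliers": int(flags.sum()) if flags is not None
                     else 0})
    return pd.DataFrame(rows)


def swarm_report(table: MeasurementTable,
                 results: Mapping[str, ComparisonResult] | None,
                 prefix: str | Path) -> tuple[Path, Path]:
    """Swarm plot (red median bars, stars, per-group N) plus a summary CSV.

    Returns ``(figure_path, summary_csv_path)``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fig_path = prefix.with_suffix(".png")
    csv_path = prefix.parent / (prefix.name + "_summary.csv")

    summary = group_summary(table)
    summary.to_csv(csv_path, index=False)

    order = table.groups
    fig, ax = plt.subplots(figsize=(1.4 * len(order) + 2, 4.5))
    sns.swarmplot(data=table.data, x="group", y="relative_activity",
                  order=order, ax=ax, size=4, color="0.3")
    for i, g in enumerate(order):
        med = summary.loc[summary["group"] == g, "median"].iloc[0]
        ax.hlines(med, i - 0.3, i + 0.3, colors="red", linewidth=2, zorder=5)
        n = summary.loc[summary["group"] == g, "n"].iloc[0]
        ax.annotate(f"N={n}", (i, ax.get_ylim()[0]),
                    xytext=(0, -28), textcoords="offset points",
                    ha="center", fontsize=8, annotation_clip=False)

    # significance brackets for pairwise comparisons
    pairwise_stars = {}
    if results:
        for res in results.values():
            for key, val in res.stars.items():
                if isinstance(key, tuple):
                    pairwise_stars[key] = val
    if pairwise_stars:
        top = float(table.data["relative_activity"].max())
        span = max(top, 1e-9)
        step = 0.08 * span
        level = top + step
        idx = {g: i for i, g in enumerate(order)}
        for (a, b), stars in sorted(pairwise_stars.items(),
                                    key=lambda kv: abs(idx[kv[0][0]]
                                                       - idx[kv[0][1]])):
            xa, xb = idx[a], idx[b]
            ax.plot([xa, xa, xb, xb],
                    [level, level + step / 3, level + step / 3, level],
                    color="black", linewidth=1)
            ax.annotate(stars, ((xa + xb) / 2, level + step / 3),
                        ha="center", va="bottom", fontsize=9)
            level += step
        ax.set_ylim(top=level + step)

    ax.set_ylabel("relative activity (GFP/RFP)")
    ax.set_xlabel("")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return fig_path, csv_path
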