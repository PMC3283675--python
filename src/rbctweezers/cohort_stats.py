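"""Cohort-level statistics and report emission.

Summaries are mean +/- standard error per storage day (optionally pooled
multi-day groups, matching the published table layout where days 29-36
share one row and days 8-22 form a plateau); group comparisons use the
two-tailed Wilcoxon rank-sum test at alpha = 0.05; headline numbers are
percent changes of cohort means.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ReportError
from .synthetic import RosEventSet

__all__ = [
    "DaySummary",
    "ComparisonResult",
    "summarize_by_day",
    "rank_sum_test",
    "percent_change",
    "ros_percent_positive",
    "build_report",
]

ALPHA = 0.05
#: largest pooled sample for which the exact null distribution is enumerated
EXACT_MAX_N = 12


@dataclass(frozen=True)
class DaySummary:
    """Mean +/- SE of one estimate over one day (or pooled day group)."""

    group: str  # e.g. "Day 1" or "Day 29 to Day 36"
    arm: str
    n: int
    mean: float
    se: float  # sample SD / sqrt(n)
    units: str  # "mV" or "dyne/cm"


@dataclass(frozen=True)
class ComparisonResult:
    """Two-tailed Wilcoxon rank-sum comparison of two cell groups."""

    group_a: str
    group_b: str
    statistic: float  # Mann-Whitney U of group_a
    p_two_tailed: float
    significant: bool  # p < 0.05
    method: str  # 'exact' | 'asymptotic'


def _summary(values: np.ndarray, group: str, arm: str, units: str) -> DaySummary:
    if values.size < 2:
        raise InsufficientDataError(f"group {group!r}: need >= 2 values, got {values.size}")
    sd = float(np.std(values, ddof=1))
    return DaySummary(
        group=group,
        arm=arm,
        n=int(values.size),
        mean=float(values.mean()),
        se=sd / math.sqrt(values.size),
        units=units,
    )


def summarize_by_day(
    estimates: pd.DataFrame,
    value_col: str,
    units: str,
    pooled: dict[str, tuple[int, ...]] | None = None,
) -> list[DaySummary]:
    """Per-day mean and SE of one estimate column.

    ``estimates`` needs columns ``day``, ``arm`` and ``value_col``.
    ``pooled`` adds labelled multi-day groups (all cells pooled, not
    mean-of-means), e.g. ``{"Day 8 to Day 22": (8, 15, 22)}``.
    """
    out: list[DaySummary] = []
    for (day, arm), grp in estimates.groupby(["day", "arm"], sort=True):
        out.append(_summary(grp[value_col].to_numpy(float), f"Day {day}", str(arm), units))
    for label, days in (pooled or {}).items():
        sel = estimates[estimates["day"].isin(days)]
        for arm, grp in sel.groupby("arm", sort=True):
            out.append(_summary(grp[value_col].to_numpy(float), label, str(arm), units))
    return out


def rank_sum_test(a, b, label_a: str = "a", label_b: str = "b") -> ComparisonResult:
    """Two-tailed Wilcoxon-Mann-Whitney test.

    Uses the exact permutation null when the pooled sample is small
    (n_a + n_b <= 12) and tie-free, otherwise the normal approximation
    with tie and continuity corrections; the branch taken is recorded in
    the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InsufficientDataError("each group needs >= 2 finite values")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        statistic=float(res.statistic),
        p_two_tailed=p,
        significant=p < ALPHA,
        method=method,
    )


def percent_change(reference: float, other: float, rounding: bool = False) -> float:
    """Signed percent change of ``other`` relative to ``reference``.

    ``100 * (other - reference) / |reference|``; with ``rounding`` the
    result is rounded to the nearest integer (headline convention).
    """
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    pct = 100.0 * (other - reference) / abs(reference)
    return float(round(pct)) if rounding else pct


def ros_percent_positive(events: RosEventSet) -> float:
    """Percent of fluorescence events above the positivity gate."""
    if events.intensities.size == 0:
        raise InsufficientDataError("no events")
    return 100.0 * float(np.mean(events.intensities > events.threshold))


def compute_headlines(
    zeta_summaries: list[DaySummary],
    elasticity_summaries: list[DaySummary],
    ros_percent_by_day: dict[int, float],
) -> dict[str, float]:
    """Headline storage-lesion percent changes from cohort summaries.

    Keys: ``zeta_decay_total_pct`` (day 1 -> final day, magnitude
    decrease), ``zeta_decay_week1_pct`` (day 1 -> pooled days 8-22),
    ``elasticity_increase_pct`` (day 8 -> day 36), ``ros_rise_week1_rel``
    (day 1 -> 8 relative rise, %), ``ros_rise_late_rel`` (day 8 -> 36).
    Entries whose inputs are absent are omitted.
    """
    zmap = {s.group: s.mean for s in zeta_summaries}
    emap = {s.group: s.mean for s in elasticity_summaries}
    headlines: dict[str, float] = {}
    day_groups = [s.group for s in zeta_summaries if s.group.startswith("Day ") and " to " not in s.group]
    if "Day 1" in zmap and day_groups:
        last = max(day_groups, key=lambda g: int(g.split()[1]))
        if last != "Day 1":
            # decay = decrease in |zeta|; zeta is negative so compare magnitudes
            headlines["zeta_decay_total_pct"] = -percent_change(
                abs(zmap["Day 1"]), abs(zmap[last])
            )
    plateau = next((s for s in zeta_summaries if " to " in s.group and s.units == "mV"
                    and set(map(int, [s.group.split()[1], s.group.split()[-1]])) == {8, 22}), None)
    if "Day 1" in zmap and plateau is not None:
        headlines["zeta_decay_week1_pct"] = -percent_change(
            abs(zmap["Day 1"]), abs(plateau.mean)
        )
    if "Day 8" in emap and "Day 36" in emap:
        headlines["elasticity_increase_pct"] = percent_change(emap["Day 8"], emap["Day 36"])
    if 1 in ros_percent_by_day and 8 in ros_percent_by_day:
        headlines["ros_rise_week1_rel"] = percent_change(
            ros_percent_by_day[1], ros_percent_by_day[8]
        )
    if 8 in ros_percent_by_day and 36 in ros_percent_by_day:
        headlines["ros_rise_late_rel"] = percent_change(
            ros_percent_by_day[8], ros_percent_by_day[36]
        )
    return headlines


def build_report(
    summaries: list[DaySummary],
    comparisons: list[ComparisonResult],
    ros_series: dict[int, float],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit deterministic CSV/JSON report artifacts.

    Writes ``summaries.csv``, ``comparisons.csv``, ``ros_series.csv``
    and ``headlines.json`` under ``out_dir`` and returns their paths.
    Zeta summaries are required; elasticity/ROS blocks are optional.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    zeta = [s for s in summaries if s.units == "mV"]
    if not zeta:
        raise ReportError("no zeta summaries to report")
    elastic = [s for s in summaries if s.units == "dyne/cm"]

    paths = {}
    df = pd.DataFrame([asdict(s) for s in summaries])
    paths["summaries"] = out_dir / "summaries.csv"
    df.to_csv(paths["summaries"], index=False)

    paths["comparisons"] = out_dir / "comparisons.csv"
    comp_cols = ["group_a", "group_b", "statistic", "p_two_tailed", "significant", "method"]
    pd.DataFrame([asdict(c) for c in comparisons], columns=comp_cols).to_csv(
        paths["comparisons"], index=False
    )

    paths["ros_series"] = out_dir / "ros_series.csv"
    pd.DataFrame(
        {"day": sorted(ros_series), "percent_positive": [ros_series[d] for d in sorted(ros_series)]}
    ).to_csv(paths["ros_series"], index=False)

    headlines = compute_headlines(zeta, elastic, ros_series)
    paths["headlines"] = out_dir / "headlines.json"
    paths["headlines"].write_text(json.dumps(headlines, indent=1, sort_keys=True))
    return paths
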