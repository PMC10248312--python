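"""Descriptive and comparative cohort statistics.

Bin frequency tables, Welch's unequal-variance t test with Cohen's d (both
pooled-SD and mean-SD variants), Pearson chi-square with Cramer's V,
fixed-window outcome construction, and conviction-record recidivism coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsError",
    "TTestResult",
    "ChiSquareResult",
    "bin_frequency_table",
    "welch_t",
    "welch_t_from_stats",
    "chi_square",
    "fixed_window_outcomes",
    "recidivism_coding",
    "DEFAULT_VIOLENT_CATEGORIES",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float  # Welch-Satterthwaite, real-valued
    p: float
    d_pooled: float
    d_mean_sd: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    cramers_v: float
    n: int


def bin_frequency_table(cohort: pd.DataFrame, by: str | None = None, n_bins: int = 9) -> pd.DataFrame:
    """Per-bin n (%), mean (SD) of total scores, plus a total row and min/max.

    ``by='sex'`` adds one block of columns per sex.  Empty bins keep an n=0
    row with undefined mean/SD.
    """
    def block(df: pd.DataFrame, prefix: str) -> dict[str, list]:
        n_total = len(df)
        cols: dict[str, list] = {f"{prefix}n": [], f"{prefix}pct": [], f"{prefix}mean": [], f"{prefix}sd": []}
        for b in range(1, n_bins + 1):
            sub = df[df["bin"] == b]["total_score"]
            cols[f"{prefix}n"].append(len(sub))
            cols[f"{prefix}pct"].append(100 * len(sub) / n_total if n_total else math.nan)
            cols[f"{prefix}mean"].append(sub.mean() if len(sub) else math.nan)
            cols[f"{prefix}sd"].append(sub.std(ddof=1) if len(sub) > 1 else math.nan)
        # total row
        cols[f"{prefix}n"].append(n_total)
        cols[f"{prefix}pct"].append(100.0 if n_total else math.nan)
        cols[f"{prefix}mean"].append(df["total_score"].mean() if n_total else math.nan)
        cols[f"{prefix}sd"].append(df["total_score"].std(ddof=1) if n_total > 1 else math.nan)
        return cols

    data: dict[str, list] = {"bin": [str(b) for b in range(1, n_bins + 1)] + ["total"]}
    data.update(block(cohort, ""))
    if by == "sex":
        for sex in sorted(cohort["sex"].unique()):
            data.update(block(cohort[cohort["sex"] == sex], f"{sex}_"))
    elif by is not None:
        raise StatsError(f"unsupported grouping {by!r}")
    return pd.DataFrame(data)


def welch_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Welch t from group summaries; d reported under both SD conventions."""
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        raise StatsError("zero variance in both groups")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    mean_sd = math.sqrt((sd1**2 + sd2**2) / 2)
    return TTestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        d_pooled=(mean1 - mean2) / pooled if pooled else math.nan,
        d_mean_sd=(mean1 - mean2) / mean_sd if mean_sd else math.nan,
    )


def welch_t(group1: Sequence[float], group2: Sequence[float]) -> TTestResult:
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    return welch_t_from_stats(
        g1.mean(), g1.std(ddof=1), g1.size, g2.mean(), g2.std(ddof=1), g2.size
    )


def chi_square(table: Sequence[Sequence[int]] | pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) with Cramer's V."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise StatsError("need a 2-d table of nonnegative counts")
    n = t.sum()
    if n == 0:
        raise StatsError("empty table")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise StatsError(f"zero margin in row {i}")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise StatsError(f"zero margin in column {j}")
    statistic, p, df, _ = stats.chi2_contingency(t, correction=False)
    k = min(t.shape[0] - 1, t.shape[1] - 1)
    v = math.sqrt(statistic / (n * k))
    return ChiSquareResult(statistic=float(statistic), df=int(df), p=float(p), cramers_v=v, n=int(n))


def fixed_window_outcomes(cohort: pd.DataFrame, outcome: str, horizon: float) -> pd.DataFrame:
    """Binary outcomes within a fixed window, with eligibility flags.

    A subject is eligible iff followed for at least the horizon OR observed to
    recidivate within it; short-follow-up non-recidivists fall out of the
    denominator.  ``horizon=inf`` reproduces overall (unfixed) outcomes.
    Columns required: ``follow_up_years``, ``{outcome}_event``,
    ``{outcome}_time_years``.
    """
    ev_col, t_col = f"{outcome}_event", f"{outcome}_time_years"
    for c in ("follow_up_years", ev_col, t_col):
        if c not in cohort.columns:
            raise StatsError(f"cohort lacks column {c!r}")
    fu = cohort["follow_up_years"].to_numpy(dtype=float)
    ev = cohort[ev_col].to_numpy(dtype=float).astype(bool)
    t = pd.to_numeric(cohort[t_col], errors="coerce").to_numpy(dtype=float)
    if (fu < 0).any() or (t[~np.isnan(t)] < 0).any():
        raise StatsError("negative follow-up or event times")
    event_in_window = ev & ~np.isnan(t) & (t <= horizon)
    if math.isinf(horizon):  # overall (unfixed) outcome: everyone eligible
        eligible = np.ones(len(cohort), dtype=bool)
    else:
        eligible = (fu >= horizon) | event_in_window
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "horizon_years": horizon,
            "eligible": eligible,
            "event": event_in_window.astype(int),
        }
    )


DEFAULT_VIOLENT_CATEGORIES = frozenset(
    {
        "assault",
        "aggravated_assault",
        "homicide",
        "attempted_homicide",
        "manslaughter",
        "robbery",
        "sexual_assault",
        "sexual_offense",
        "kidnapping",
        "forcible_confinement",
        "uttering_threats",
        "weapons_violence",
    }
)


def recidivism_coding(
    convictions: pd.DataFrame,
    violent_categories: frozenset[str] | set[str] = DEFAULT_VIOLENT_CATEGORIES,
    nonviolent_categories: frozenset[str] | set[str] | None = None,
    unknown: str = "error",
) -> pd.DataFrame:
    """Per-subject violent/general flags and first-event times from conviction
    records (columns: subject_id, offense_category, time_years).

    Violent convictions are those in ``violent_categories`` (sexual offenses
    included by default); every conviction counts as general, so violent
    implies general.  When ``nonviolent_categories`` is supplied, categories
    in neither list are unknown: ``unknown='error'`` rejects them, while
    ``'nonviolent'`` treats them as general-only with a warning.
    """
    import warnings

    for c in ("subject_id", "offense_category", "time_years"):
        if c not in convictions.columns:
            raise StatsError(f"convictions lack column {c!r}")
    if (pd.to_numeric(convictions["time_years"], errors="coerce") < 0).any():
        raise StatsError("negative conviction times")

    rows = []
    for sid, grp in convictions.groupby("subject_id", sort=True):
        v_times, g_times = [], []
        for _, rec in grp.iterrows():
            cat = str(rec["offense_category"])
            t = float(rec["time_years"])
            g_times.append(t)
            if cat in violent_categories:
                v_times.append(t)
            elif nonviolent_categories is not None and cat not in nonviolent_categories:
                if unknown == "error":
                    raise StatsError(f"unknown offense category {cat!r}")
                warnings.warn(f"unknown offense category {cat!r} treated as nonviolent")
        rows.append(
            {
                "subject_id": sid,
                "violent_event": int(bool(v_times)),
                "violent_time_years": min(v_times) if v_times else math.nan,
                "general_event": int(bool(g_times)),
                "general_time_years": min(g_times) if g_times else math.nan,
            }
        )
    return pd.DataFrame(rows)
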