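"""Rank-based discrimination: AUC with confidence intervals and effect labels.

The AUC is the Mann-Whitney probability that a randomly selected case scores
above a randomly selected non-case, with ties counted one half.  The default
standard error is Hanley-McNeil; a nonparametric bootstrap interval is
available by flag.  Effect-size labels follow the conventional AUC thresholds
.556 / .639 / .714 for small / medium / large.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DiscriminationError",
    "ROCResult",
    "roc_auc",
    "effect_label",
    "roc_coordinates",
    "subgroup_discrimination",
]

EFFECT_THRESHOLDS = {"small": 0.556, "medium": 0.639, "large": 0.714}
UNSTABLE_MIN_CLASS = 5  # fewer cases/non-cases than this flags the estimate


class DiscriminationError(ValueError):
    pass


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_recidivists: int
    n_nonrecidivists: int
    effect_label: str
    unstable: bool
    ci_method: str = "hanley-mcneil"


def effect_label(auc: float) -> str:
    """Map an AUC in [0, 1] onto {below-small, small, medium, large}."""
    if not 0 <= auc <= 1:
        raise DiscriminationError(f"AUC {auc} outside [0, 1]")
    if auc >= EFFECT_THRESHOLDS["large"]:
        return "large"
    if auc >= EFFECT_THRESHOLDS["medium"]:
        return "medium"
    if auc >= EFFECT_THRESHOLDS["small"]:
        return "small"
    return "below-small"


def _auc_midrank(scores: np.ndarray, outcomes: np.ndarray) -> float:
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    ranks = rankdata(scores)  # midranks handle ties
    r1 = ranks[outcomes == 1].sum()
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(
    scores: Sequence[float],
    outcomes: Sequence[int],
    ci: str = "hanley-mcneil",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> ROCResult:
    """Mann-Whitney AUC with SE and a 95% CI clipped to [0, 1].

    Parameters
    ----------
    ci : {'hanley-mcneil', 'bootstrap'}
        CI method; bootstrap resamples subjects with replacement.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise DiscriminationError("scores and outcomes must be equal-length 1-d")
    if not set(np.unique(y)) <= {0, 1}:
        raise DiscriminationError("outcomes must be binary 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise DiscriminationError("AUC undefined: only one outcome class present")

    auc = _auc_midrank(s, y)
    se = _hanley_mcneil_se(auc, n1, n0)
    if ci == "hanley-mcneil":
        lo, hi = auc - 1.96 * se, auc + 1.96 * se
    elif ci == "bootstrap":
        rng = rng or np.random.default_rng()
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(y.size, size=y.size)
            yb = y[idx]
            if yb.sum() in (0, yb.size):
                continue
            stats.append(_auc_midrank(s[idx], yb))
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        raise DiscriminationError(f"unknown CI method {ci!r}")
    lo, hi = float(max(lo, 0.0)), float(min(hi, 1.0))
    return ROCResult(
        auc=float(auc),
        se=se,
        ci95=(lo, hi),
        n_recidivists=n1,
        n_nonrecidivists=n0,
        effect_label=effect_label(auc),
        unstable=min(n1, n0) < UNSTABLE_MIN_CLASS,
        ci_method=ci,
    )


def roc_coordinates(scores: Sequence[float], outcomes: Sequence[int]) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold) for export."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    thresholds = np.unique(s)[::-1]
    n1, n0 = int(y.sum()), int((1 - y).sum())
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        pred = s >= t
        rows.append(
            {
                "threshold": float(t),
                "fpr": float((pred & (y == 0)).sum() / n0),
                "tpr": float((pred & (y == 1)).sum() / n1),
            }
        )
    return pd.DataFrame(rows)


def subgroup_discrimination(
    cohort: pd.DataFrame,
    grouping: str | None,
    outcomes: Iterable[str] = ("violent", "general"),
    horizons: Iterable[float] = (5.0, 10.0, float("inf")),
    measures: Iterable[str] = ("total_score", "bin"),
    ci: str = "hanley-mcneil",
) -> tuple[pd.DataFrame, list[str]]:
    """One AUC row per (subgroup, measure, outcome, horizon).

    ``grouping`` is None (whole cohort), 'sex', or 'diagnosis' (membership in
    each diagnosis label, overlapping groups).  Subgroups without both outcome
    classes are skipped, with the reason returned in the second element.
    Results with very few cases in either class carry ``unstable=True``.
    """
    from .cohort_stats import fixed_window_outcomes

    if grouping is None:
        groups: list[tuple[str, pd.DataFrame]] = [("all", cohort)]
    elif grouping == "sex":
        groups = [(str(k), g) for k, g in cohort.groupby("sex")]
    elif grouping == "diagnosis":
        labels = sorted(
            {d for cell in cohort["diagnoses"].fillna("") for d in str(cell).split(";") if d}
        )
        groups = [
            (lab, cohort[cohort["diagnoses"].fillna("").str.split(";").map(lambda ds, lab=lab: lab in ds)])
            for lab in labels
        ]
    else:
        raise DiscriminationError(f"unknown grouping {grouping!r}")

    rows = []
    skipped: list[str] = []
    for gname, gdf in groups:
        if gdf.empty:
            skipped.append(f"{gname}: empty subgroup")
            continue
        for outcome in outcomes:
            for horizon in horizons:
                fw = fixed_window_outcomes(gdf, outcome, horizon)
                eligible = fw[fw["eligible"]]
                y = eligible["event"].to_numpy()
                if y.size == 0 or y.sum() == 0 or y.sum() == y.size:
                    skipped.append(
                        f"{gname}/{outcome}/horizon={horizon}: insufficient recidivists or nonrecidivists"
                    )
                    continue
                sub = gdf.set_index("subject_id").loc[eligible["subject_id"]]
                for measure in measures:
                    res = roc_auc(sub[measure].to_numpy(dtype=float), y, ci=ci)
                    rows.append(
                        {
                            "subgroup": gname,
                            "measure": measure,
                            "outcome": outcome,
                            "horizon": horizon,
                            "auc": res.auc,
                            "se": res.se,
                            "ci_lo": res.ci95[0],
                            "ci_hi": res.ci95[1],
                            "n_recidivists": res.n_recidivists,
                            "n_nonrecidivists": res.n_nonrecidivists,
                            "effect": res.effect_label,
                            "unstable": res.unstable,
                        }
                    )
    return pd.DataFrame(rows), skipped
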