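"""Calibration machinery: logistic score-to-rate models, Hosmer-Lemeshow
goodness of fit, norms-based expected counts, and the E/O index.

The E/O index is the ratio of the expected number of recidivists (per-bin
normative rates times bin sizes, summed) to the observed number.  Its 95%
interval is multiplicative: ``(E/O) * exp(+-1.96 * sqrt(1/O))``; the index is
flagged significant when the interval excludes 1.0.

The logistic fit is a two-parameter maximum-likelihood fit (intercept plus a
per-point slope) computed by iteratively reweighted least squares, with
standard errors from the observed information matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "CalibrationError",
    "SeparationError",
    "ConvergenceError",
    "LogisticFit",
    "NormsTable",
    "EOResult",
    "HLResult",
    "fit_logistic",
    "predict_rate",
    "recidivism_curve",
    "hosmer_lemeshow",
    "expected_counts",
    "eo_index",
    "calibration_report",
    "default_norms",
    "load_norms",
]


class CalibrationError(ValueError):
    pass


class SeparationError(CalibrationError):
    """Complete separation: the score perfectly splits cases from non-cases."""


class ConvergenceError(CalibrationError):
    def __init__(self, message: str, loglik_trace: list[float]):
        super().__init__(message)
        self.loglik_trace = loglik_trace


@dataclass(frozen=True)
class LogisticFit:
    b0: float
    b1: float
    se_b0: float
    se_b1: float
    wald: float
    p_value: float
    odds_ratio: float
    or_ci95: tuple[float, float]
    converged: bool
    n: int
    n_events: int
    loglik: float
    n_iter: int


def fit_logistic(
    scores: Sequence[float],
    outcomes: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """ML logistic regression of a binary outcome on a single score.

    Convergence: relative log-likelihood change below ``tol`` (default 1e-10)
    within ``max_iter`` iterations.  Complete separation raises
    :class:`SeparationError`; non-convergence raises :class:`ConvergenceError`
    carrying the log-likelihood trace.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("scores and outcomes must be equal-length 1-d")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise CalibrationError("outcomes must be binary 0/1")
    n = x.size
    n_events = int(y.sum())
    if n < 10:
        raise CalibrationError("need at least 10 observations")
    if n_events == 0 or n_events == n:
        raise CalibrationError("both outcome classes must be present")
    if x.min() == x.max():
        # degenerate constant score: intercept-only fit with the closed-form
        # MLE b0 = logit of the base rate (b1 fixed at 0, no slope inference)
        p = n_events / n
        b0 = math.log(p / (1 - p))
        se0 = math.sqrt(1 / (n * p * (1 - p)))
        ll = n_events * math.log(p) + (n - n_events) * math.log(1 - p)
        return LogisticFit(
            b0=b0, b1=0.0, se_b0=se0, se_b1=math.nan, wald=math.nan,
            p_value=math.nan, odds_ratio=1.0, or_ci95=(math.nan, math.nan),
            converged=True, n=n, n_events=n_events, loglik=ll, n_iter=0,
        )
    s1, s0 = x[y == 1], x[y == 0]
    if s1.min() > s0.max() or s1.max() < s0.min():
        raise SeparationError("complete separation: score perfectly divides the classes")

    X = np.column_stack([np.ones(n), x])
    beta = np.array([math.log(n_events / (n - n_events)), 0.0])
    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        trace.append(ll)
        if it > 1 and abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            converged = True
            break
        ll_old = ll
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ z)
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations", trace)

    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    wald = float((beta[1] / se[1]) ** 2)
    p = float(chi2.sf(wald, df=1))
    z975 = norm.ppf(0.975)
    or_ci = (math.exp(beta[1] - z975 * se[1]), math.exp(beta[1] + z975 * se[1]))
    return LogisticFit(
        b0=float(beta[0]),
        b1=float(beta[1]),
        se_b0=float(se[0]),
        se_b1=float(se[1]),
        wald=wald,
        p_value=p,
        odds_ratio=float(math.exp(beta[1])),
        or_ci95=or_ci,
        converged=True,
        n=n,
        n_events=n_events,
        loglik=trace[-1],
        n_iter=len(trace),
    )


def predict_rate(fit: LogisticFit, score: float | np.ndarray) -> float | np.ndarray:
    """Event rate at a score: ``exp(b0 + b1*s) / (1 + exp(b0 + b1*s))``."""
    out = expit(fit.b0 + fit.b1 * np.asarray(score, dtype=float))
    return float(out) if np.isscalar(score) or np.ndim(score) == 0 else out


def recidivism_curve(
    fit: LogisticFit,
    score_range: tuple[int, int] | None = None,
    scores: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tabulated score -> rate over an inclusive integer range, or over the
    observed scores only (e.g., restricting a subgroup curve to the scores it
    actually contains)."""
    if scores is not None:
        grid = np.unique(np.asarray(scores, dtype=float))
    else:
        if score_range is None:
            raise CalibrationError("need score_range or scores")
        lo, hi = score_range
        grid = np.arange(int(lo), int(hi) + 1, dtype=float)
    return pd.DataFrame({"score": grid, "rate": predict_rate(fit, grid)})


# --- Hosmer-Lemeshow ------------------------------------------------------


@dataclass(frozen=True)
class HLResult:
    statistic: float
    df: int
    p_value: float
    groups: pd.DataFrame  # per-group: p_lo, p_hi, n, observed, expected


def hosmer_lemeshow(
    fitted_probs: Sequence[float],
    outcomes: Sequence[int],
    n_groups: int = 10,
) -> HLResult:
    """Goodness of fit across risk-decile groups of the fitted probabilities.

    Subjects with identical fitted probabilities always share a group, so the
    effective group count can fall below ``n_groups``.  The statistic is
    ``sum (O - E)^2 / (E (1 - E/n))`` over groups, referred to chi-square with
    ``groups - 2`` degrees of freedom.
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise CalibrationError("fitted_probs and outcomes must be equal-length 1-d")
    if n_groups < 2:
        raise CalibrationError("n_groups must be >= 2")
    if np.ptp(p) == 0:
        raise CalibrationError("degenerate grouping: all fitted probabilities are equal")

    edges = np.quantile(p, np.linspace(0, 1, n_groups + 1)[1:-1])
    group = np.searchsorted(edges, p, side="right")
    labels = np.unique(group)
    if labels.size < 3:
        raise CalibrationError("degenerate grouping: fewer than 3 distinct risk groups")

    rows = []
    stat = 0.0
    for g in labels:
        mask = group == g
        ng = int(mask.sum())
        obs = float(y[mask].sum())
        exp = float(p[mask].sum())
        denom = exp * (1 - exp / ng)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
        elif obs != exp:
            stat = math.inf
        rows.append(
            {
                "p_lo": float(p[mask].min()),
                "p_hi": float(p[mask].max()),
                "n": ng,
                "observed": obs,
                "expected": exp,
            }
        )
    df = labels.size - 2
    return HLResult(
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df=df)),
        groups=pd.DataFrame(rows),
    )


# --- norms and E/O --------------------------------------------------------


@dataclass(frozen=True)
class NormsTable:
    """Per-bin expected event rates from a reference sample."""

    rates: Mapping[int, float]
    horizon: float
    outcome: str = "violent"
    source: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", dict(self.rates))
        for b, r in self.rates.items():
            if not 0 <= r <= 1:
                raise CalibrationError(f"bin {b}: rate {r} outside [0, 1]")

    def rate(self, bin_number: int) -> float:
        try:
            return self.rates[bin_number]
        except KeyError:
            raise CalibrationError(f"norms have no rate for bin {bin_number}") from None


#: Reference five-year violent-recidivism rates per bin for the default
#: nine-bin instrument (normative development sample).
DEFAULT_NORM_RATES = {1: 0.08, 2: 0.09, 3: 0.18, 4: 0.19, 5: 0.25, 6: 0.37, 7: 0.45, 8: 0.58, 9: 0.80}


def default_norms() -> NormsTable:
    return NormsTable(rates=dict(DEFAULT_NORM_RATES), horizon=5.0, outcome="violent", source="development-sample")


def load_norms(path: str | Path) -> NormsTable:
    d = yaml.safe_load(Path(path).read_text())
    return NormsTable(
        rates={int(k): float(v) for k, v in d["rates"].items()},
        horizon=float(d.get("horizon", 5.0)),
        outcome=str(d.get("outcome", "violent")),
        source=str(d.get("source", "file")),
    )


def expected_counts(norms: NormsTable, bin_sizes: Mapping[int, int]) -> dict[int, float]:
    """Expected recidivist count per bin: rate times n, unrounded."""
    return {b: norms.rate(b) * n for b, n in bin_sizes.items()}


@dataclass(frozen=True)
class EOResult:
    eo: float | None  # None when O == 0
    ci95: tuple[float, float] | None
    significant: bool | None
    expected: float
    observed: int


def eo_index(expected: float, observed: int) -> EOResult:
    """E/O with multiplicative 95% CI ``(E/O) * exp(-+1.96 sqrt(1/O))``.

    With zero observed events the index is undefined: the row is returned with
    the expected count only and no CI.
    """
    if expected < 0:
        raise CalibrationError("expected count must be >= 0")
    if observed < 0:
        raise CalibrationError("observed count must be >= 0")
    if observed == 0:
        return EOResult(eo=None, ci95=None, significant=None, expected=expected, observed=0)
    eo = expected / observed
    half = 1.96 * math.sqrt(1.0 / observed)
    ci = (eo * math.exp(-half), eo * math.exp(half))
    return EOResult(
        eo=eo,
        ci95=ci,
        significant=not (ci[0] <= 1.0 <= ci[1]),
        expected=expected,
        observed=observed,
    )


def calibration_report(
    cohort: pd.DataFrame,
    norms: NormsTable,
    outcome: str = "violent",
    horizon: float = 5.0,
    expected_override: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Per-bin plus total expected/observed table against reference norms.

    Only subjects eligible for the fixed window (followed for at least the
    horizon, or recidivating within it) enter the denominators.  Expected
    counts are rate x n, unrounded; an ``expected_override`` mapping replaces
    individual bin E values (e.g., to use externally published counts).  Bins
    with zero observed events carry an undefined index and no CI but still
    enter the totals.
    """
    from .cohort_stats import fixed_window_outcomes

    fw = fixed_window_outcomes(cohort, outcome, horizon)
    eligible = fw[fw["eligible"]]
    sub = cohort.set_index("subject_id").loc[eligible["subject_id"]]
    bins = sub["bin"].to_numpy(dtype=int)
    events = eligible["event"].to_numpy(dtype=int)

    present = sorted(set(bins.tolist()))
    for b in present:
        norms.rate(b)  # hard error if a populated bin has no norm

    all_bins = sorted(set(norms.rates) | set(present))
    rows = []
    for b in all_bins:
        mask = bins == b
        n_b = int(mask.sum())
        obs = int(events[mask].sum())
        rate = norms.rate(b)
        exp = rate * n_b
        if expected_override and b in expected_override:
            exp = float(expected_override[b])
        res = eo_index(exp, obs)
        rows.append(
            {
                "bin": b,
                "n": n_b,
                "expected_rate": rate,
                "expected": exp,
                "observed": obs,
                "observed_rate": obs / n_b if n_b else math.nan,
                "eo": res.eo,
                "ci_lo": res.ci95[0] if res.ci95 else None,
                "ci_hi": res.ci95[1] if res.ci95 else None,
                "significant": res.significant,
            }
        )
    total_n = int(sum(r["n"] for r in rows))
    total_e = float(sum(r["expected"] for r in rows))
    total_o = int(sum(r["observed"] for r in rows))
    res = eo_index(total_e, total_o)
    rows.append(
        {
            "bin": "total",
            "n": total_n,
            "expected_rate": total_e / total_n if total_n else math.nan,
            "expected": total_e,
            "observed": total_o,
            "observed_rate": total_o / total_n if total_n else math.nan,
            "eo": res.eo,
            "ci_lo": res.ci95[0] if res.ci95 else None,
            "ci_hi": res.ci95[1] if res.ci95 else None,
            "significant": res.significant,
        }
    )
    return pd.DataFrame(rows)


def plot_calibration(
    curves: Mapping[str, pd.DataFrame],
    report: pd.DataFrame | None,
    spec_bins: Sequence[tuple[int, int]] | None,
    path: str | Path,
) -> None:
    """Model curves as lines with per-bin observed rates as points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, curve in curves.items():
        ax.plot(curve["score"], curve["rate"], label=label)
    if report is not None and spec_bins is not None:
        pts = report[report["bin"] != "total"]
        mids = {i + 1: (lo + hi) / 2 for i, (lo, hi) in enumerate(spec_bins)}
        xs = [mids[int(b)] for b in pts["bin"] if int(b) in mids]
        ys = [r for b, r in zip(pts["bin"], pts["observed_rate"]) if int(b) in mids]
        ax.scatter(xs, ys, color="black", zorder=3, label="observed (per bin)")
    ax.set_xlabel("total score")
    ax.set_ylabel("event rate")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
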