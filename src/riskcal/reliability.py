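"""Interrater and internal-consistency battery.

Covers the paired-rater agreement coefficients used for ordinal risk-category
ratings — intraclass correlation (one-way and two-way single-measure), Cohen's
kappa (unweighted / linear / quadratic), Gwet's AC1 and weighted AC2, percent
agreement (binary and weighted) — plus Cronbach's alpha for item matrices.

Ordinal weights share one kernel across weighted kappa, AC2 and weighted
percent agreement: quadratic by default, linear selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "ReliabilityError",
    "ICCResult",
    "AgreementResult",
    "icc_single",
    "cohen_kappa",
    "gwet",
    "percent_agreement",
    "cronbach_alpha",
    "weight_matrix",
    "reliability_report",
]


class ReliabilityError(ValueError):
    pass


def weight_matrix(categories: Sequence, scheme: str) -> np.ndarray:
    """Agreement weights over an ordered category set.

    'identity' gives 1 on the diagonal only; 'linear' and 'quadratic' decay
    with category distance scaled to the full range.
    """
    q = len(categories)
    if q < 1:
        raise ReliabilityError("empty category set")
    i, j = np.meshgrid(np.arange(q), np.arange(q), indexing="ij")
    if scheme == "identity":
        return (i == j).astype(float)
    if q == 1:
        return np.ones((1, 1))
    d = np.abs(i - j) / (q - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ReliabilityError(f"unknown weight scheme {scheme!r}")


def _pair_arrays(r1: Sequence, r2: Sequence) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ReliabilityError("rating vectors must be equal-length 1-d")
    if a.size == 0:
        raise ReliabilityError("no ratings supplied")
    return a, b


def _category_index(a: np.ndarray, b: np.ndarray, categories: Sequence | None) -> tuple[np.ndarray, np.ndarray, list]:
    cats = sorted(set(a.tolist()) | set(b.tolist())) if categories is None else list(categories)
    lookup = {c: k for k, c in enumerate(cats)}
    try:
        ia = np.array([lookup[v] for v in a.tolist()])
        ib = np.array([lookup[v] for v in b.tolist()])
    except KeyError as err:
        raise ReliabilityError(f"rating {err.args[0]!r} outside the category set") from None
    return ia, ib, cats


# --- ICC ------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci95: tuple[float, float]
    model: str
    n_subjects: int
    n_raters: int


def icc_single(
    ratings: Sequence[Sequence[float]],
    model: str = "oneway",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measure intraclass correlation from a subjects x raters matrix.

    Models: 'oneway' (one-way random effects, absolute agreement),
    'twoway_consistency', 'twoway_agreement'.  One-way and consistency CIs use
    exact F bounds; the two-way agreement CI uses the Satterthwaite
    approximation.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ReliabilityError("ratings must be a 2-d subjects x raters matrix")
    n, k = X.shape
    if k < 2 or n < 5:
        raise ReliabilityError("need at least 2 raters and 5 subjects")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)

    msr = ss_rows / (n - 1)

    if model == "oneway":
        ss_within = ss_total - ss_rows
        msw = ss_within / (n * (k - 1))
        if msr == 0:
            warnings.warn("zero between-subject variance; ICC set to 0")
            return ICCResult(0.0, (0.0, 0.0), model, n, k)
        icc = (msr - msw) / (msr + (k - 1) * msw)
        if msw == 0:
            return ICCResult(1.0, (1.0, 1.0), model, n, k)
        F = msr / msw
        fl = F / f_dist.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = F * f_dist.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return ICCResult(float(icc), (float(lo), float(hi)), model, n, k)

    mse_ss = ss_total - ss_rows - ss_cols
    mse = mse_ss / ((n - 1) * (k - 1))
    msc = ss_cols / (k - 1)

    if model == "twoway_consistency":
        if mse == 0:
            return ICCResult(1.0, (1.0, 1.0), model, n, k)
        icc = (msr - mse) / (msr + (k - 1) * mse)
        F = msr / mse
        fl = F / f_dist.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = F * f_dist.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return ICCResult(float(icc), (float(lo), float(hi)), model, n, k)

    if model == "twoway_agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom == 0:
            warnings.warn("zero total variance; ICC set to 0")
            return ICCResult(0.0, (0.0, 0.0), model, n, k)
        icc = (msr - mse) / denom
        if mse == 0 and msc == mse:
            return ICCResult(1.0, (1.0, 1.0), model, n, k)
        r = icc
        a = (k * r) / (n * (1 - r)) if r < 1 else math.inf
        b = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r < 1 else math.inf
        v = ((a * msc + b * mse) ** 2) / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_lo = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_hi = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_lo * mse)) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = (n * (f_hi * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
        return ICCResult(float(icc), (float(lo), float(hi)), model, n, k)

    raise ReliabilityError(f"unknown ICC model {model!r}")


# --- chance-corrected agreement ------------------------------------------


def cohen_kappa(
    r1: Sequence,
    r2: Sequence,
    weights: str = "none",
    categories: Sequence | None = None,
) -> float:
    """Cohen's kappa for two raters; weights in {'none', 'linear', 'quadratic'}.

    Returns NaN when both raters use a single common category (chance
    agreement is 1 and the coefficient is undefined).
    """
    a, b = _pair_arrays(r1, r2)
    ia, ib, cats = _category_index(a, b, categories)
    q = len(cats)
    scheme = "identity" if weights == "none" else weights
    w = weight_matrix(cats, scheme)
    table = np.zeros((q, q))
    np.add.at(table, (ia, ib), 1.0)
    p = table / table.sum()
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)
    po = float(np.sum(w * p))
    pe = float(p1 @ w @ p2)
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1 - pe)


@dataclass(frozen=True)
class AgreementResult:
    value: float
    se: float
    ci95: tuple[float, float]
    variant: str
    weights: str


def gwet(
    r1: Sequence,
    r2: Sequence,
    variant: str = "AC1",
    weights: str = "quadratic",
    categories: Sequence | None = None,
    alpha: float = 0.05,
) -> AgreementResult:
    """Gwet's AC1 (unweighted) or AC2 (ordinal-weighted) with a 95% CI.

    Chance agreement uses average category prevalences:
    ``pe = Tw / (q(q-1)) * sum_k pi_k (1 - pi_k)`` with ``Tw`` the sum of all
    weights (identity weights for AC1 reduce this to ``1/(q-1) * sum ...``).
    The variance follows Gwet's subject-level linearization; the CI is
    t-based with n-1 degrees of freedom, clipped to [-1, 1].
    """
    a, b = _pair_arrays(r1, r2)
    ia, ib, cats = _category_index(a, b, categories)
    q = len(cats)
    n = a.size
    if variant == "AC1":
        w = weight_matrix(cats, "identity")
        wname = "identity"
    elif variant == "AC2":
        w = weight_matrix(cats, weights)
        wname = weights
    else:
        raise ReliabilityError(f"unknown Gwet variant {variant!r}")

    pi = np.zeros(q)
    np.add.at(pi, ia, 0.5 / n)
    np.add.at(pi, ib, 0.5 / n)
    tw = float(w.sum())
    if q < 2:
        raise ReliabilityError("need at least 2 categories in the set")
    pe = tw / (q * (q - 1)) * float(np.sum(pi * (1 - pi)))
    pa_i = w[ia, ib]
    pa = float(pa_i.mean())
    if pe == 1.0:
        raise ReliabilityError("degenerate chance agreement (pe = 1)")
    ac = (pa - pe) / (1 - pe)

    # subject-level linearization for the variance
    onehot = np.zeros((n, q))
    onehot[np.arange(n), ia] += 0.5
    onehot[np.arange(n), ib] += 0.5
    pe_i = tw / (q * (q - 1)) * (onehot @ (1 - pi))
    ac_i = (pa_i - pe) / (1 - pe)
    ac_star = ac_i - 2 * (1 - ac) * (pe_i - pe) / (1 - pe)
    var = float(np.sum((ac_star - ac) ** 2)) / (n * (n - 1)) if n > 1 else 0.0
    se = math.sqrt(max(var, 0.0))
    tcrit = float(t_dist.ppf(1 - alpha / 2, n - 1)) if n > 1 else math.inf
    lo = max(ac - tcrit * se, -1.0)
    hi = min(ac + tcrit * se, 1.0)
    return AgreementResult(value=float(ac), se=se, ci95=(lo, hi), variant=variant, weights=wname)


def percent_agreement(
    r1: Sequence,
    r2: Sequence,
    weights: str = "binary",
    scheme: str = "quadratic",
    categories: Sequence | None = None,
) -> float:
    """Mean per-subject agreement weight.

    'binary' counts exact matches; 'ordinal' applies the distance kernel
    (same kernel as weighted AC2/kappa, default quadratic).
    """
    a, b = _pair_arrays(r1, r2)
    ia, ib, cats = _category_index(a, b, categories)
    if weights == "binary":
        w = weight_matrix(cats, "identity")
    elif weights == "ordinal":
        w = weight_matrix(cats, scheme)
    else:
        raise ReliabilityError(f"unknown percent-agreement weights {weights!r}")
    return float(w[ia, ib].mean())


def cronbach_alpha(items: Sequence[Sequence[float]]) -> float:
    """Cronbach's alpha from a subjects x items matrix:
    ``k/(k-1) * (1 - sum(item variances) / variance(totals))``."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ReliabilityError("need a 2-d matrix with at least 2 items")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def reliability_report(
    totals_1: Sequence[float],
    totals_2: Sequence[float],
    bins_1: Sequence[int],
    bins_2: Sequence[int],
    categories: Sequence[int] | None = None,
    weight_scheme: str = "quadratic",
    item_matrix: Sequence[Sequence[float]] | None = None,
) -> dict:
    """Battery of agreement statistics for a double-coded subsample."""
    mat = np.column_stack([totals_1, totals_2])
    icc1 = icc_single(mat, "oneway")
    iccc = icc_single(mat, "twoway_consistency")
    ac1 = gwet(bins_1, bins_2, "AC1", categories=categories)
    ac2 = gwet(bins_1, bins_2, "AC2", weights=weight_scheme, categories=categories)
    out = {
        "icc_oneway": {"value": icc1.value, "ci95": list(icc1.ci95)},
        "icc_consistency": {"value": iccc.value, "ci95": list(iccc.ci95)},
        "kappa_unweighted": cohen_kappa(bins_1, bins_2, "none", categories),
        "kappa_weighted": cohen_kappa(bins_1, bins_2, weight_scheme, categories),
        "kappa_weight_scheme": weight_scheme,
        "ac1": {"value": ac1.value, "ci95": list(ac1.ci95)},
        "ac2": {"value": ac2.value, "ci95": list(ac2.ci95), "weights": ac2.weights},
        "pct_agreement_binary": percent_agreement(bins_1, bins_2, "binary", categories=categories),
        "pct_agreement_weighted": percent_agreement(
            bins_1, bins_2, "ordinal", scheme=weight_scheme, categories=categories
        ),
    }
    if item_matrix is not None:
        out["alpha"] = cronbach_alpha(item_matrix)
    return out
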