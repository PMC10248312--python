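"""Seeded synthetic cohorts with the statistical structure the analyses assume.

Cohorts emulate a binned actuarial-instrument population: a male/female mix
with sex-specific total-score distributions, fixed-horizon binary recidivism
outcomes generated from logistic score-to-rate models, diagnostic labels with
pairwise comorbidity targets, item-level score sheets with injected
missingness, and a noisy second rater for agreement analyses.

Scores are drawn from a truncated normal on the instrument's score range and
rounded to integers.  The truncated-normal location is solved numerically so
the *post-truncation* mean matches the configured target mean (truncation
would otherwise bias the mean upward); the scale is kept at the configured SD.

Reproducibility: one global integer seed governs everything.  Sub-streams are
derived as ``np.random.default_rng([seed, STREAM_ID])`` with fixed stream ids
(0 cohort, 1 item sheets, 2 second rater), so each stage is independently
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .instrument import InstrumentSpec, ScoreSheet, assign_bin, default_spec

__all__ = [
    "ConfigError",
    "OutcomeModel",
    "SimulationParams",
    "CohortRecord",
    "generate_cohort",
    "generate_item_sheets",
    "generate_rater_pair",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort",
    "read_cohort",
    "default_params",
]

STREAM_COHORT = 0
STREAM_SHEETS = 1
STREAM_RATER = 2


class ConfigError(ValueError):
    """Invalid or inconsistent simulation parameters."""


@dataclass(frozen=True)
class OutcomeModel:
    """Per-point logistic model: P(event by horizon) = expit(b0 + b1 * score)."""

    b0: float
    b1: float


@dataclass
class SimulationParams:
    n_subjects: int = 478
    prop_male: float = 0.831
    # per-sex (mean, sd) of the integer total score, truncated to spec range
    score_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (-4.81, 19.1), "female": (-16.61, 14.9)}
    )
    # (outcome, horizon_years) -> logistic coefficients
    outcome_models: dict[tuple[str, float], OutcomeModel] = field(
        default_factory=lambda: {
            ("violent", 5.0): OutcomeModel(-2.856, 0.040),
            ("violent", 10.0): OutcomeModel(-2.471, 0.041),
            ("general", 5.0): OutcomeModel(-2.33, 0.040),
            ("general", 10.0): OutcomeModel(-1.93, 0.041),
        }
    )
    diagnosis_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "psychosis": 0.845,
            "sud": 0.562,
            "mood": 0.387,
            "aspd": 0.245,
        }
    )
    # (diagnosis_a, diagnosis_b) -> target odds multiplier for co-occurrence
    comorbidity: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("psychosis", "sud"): 0.73,
            ("mood", "sud"): 0.73,
            ("aspd", "sud"): 3.6,
        }
    )
    follow_up_range: tuple[float, float] = (1.0, 25.0)
    missing_item_rate: float = 0.0
    rater_disagreement: float = 0.2
    rater_kernel: str = "adjacent"  # or "uniform"
    rater_magnitude: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.prop_male <= 1:
            raise ConfigError("prop_male must be in [0, 1]")
        if not 0 <= self.missing_item_rate <= 1:
            raise ConfigError("missing_item_rate must be in [0, 1]")
        if not 0 <= self.rater_disagreement <= 1:
            raise ConfigError("rater_disagreement must be in [0, 1]")
        if self.rater_kernel not in ("adjacent", "uniform"):
            raise ConfigError(f"unknown rater kernel {self.rater_kernel!r}")
        for sex, (mean, sd) in self.score_model.items():
            if sd <= 0:
                raise ConfigError(f"score SD for {sex!r} must be > 0")
        if not self.outcome_models:
            raise ConfigError("at least one outcome model is required")
        for (outcome, horizon) in self.outcome_models:
            if horizon <= 0:
                raise ConfigError(f"horizon for {outcome!r} must be positive")
        for label, p in self.diagnosis_prevalence.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"prevalence for {label!r} must be in [0, 1]")
        for (a, b), m in self.comorbidity.items():
            if m <= 0:
                raise ConfigError(f"comorbidity multiplier for ({a}, {b}) must be > 0")
            if a not in self.diagnosis_prevalence or b not in self.diagnosis_prevalence:
                raise ConfigError(f"comorbidity pair ({a}, {b}) references unknown diagnosis")
        lo, hi = self.follow_up_range
        if not 0 < lo <= hi:
            raise ConfigError("follow_up_range must satisfy 0 < lo <= hi")

    def outcomes(self) -> list[str]:
        return sorted({o for o, _ in self.outcome_models})

    def horizons(self, outcome: str) -> list[float]:
        return sorted(h for o, h in self.outcome_models if o == outcome)


def default_params(**overrides) -> SimulationParams:
    p = SimulationParams()
    return replace(p, **overrides) if overrides else p


@dataclass
class CohortRecord:
    subject_id: str
    sex: str
    diagnoses: frozenset[str]
    total_score: int
    bin: int
    follow_up_years: float
    # outcome -> observed first-event flag / time (None when no observed event)
    events: dict[str, bool]
    event_times: dict[str, float | None]
    item_weights: dict[str, int] | None = None


# --- score distribution ---------------------------------------------------


def _truncnorm_location(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location mu such that a TruncNormal(mu, sd) on [lo, hi] has the target mean."""

    def post_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd)

    span = hi - lo
    return brentq(lambda m: post_mean(m) - target_mean, lo - 3 * span, hi + 3 * span, xtol=1e-9)


def _truncnorm_params(target_mean: float, target_sd: float, lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) such that the truncated normal on [lo, hi] has the target
    post-truncation mean and SD.  Falls back to matching the mean only (at
    sigma = target_sd) when no exact two-moment solution is found."""
    from scipy.optimize import fsolve

    def moments(p):
        mu, sig = p
        sig = abs(sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        return [
            truncnorm.mean(a, b, loc=mu, scale=sig) - target_mean,
            truncnorm.std(a, b, loc=mu, scale=sig) - target_sd,
        ]

    sol, info, ier, _ = fsolve(moments, [target_mean, target_sd * 1.5], full_output=True)
    if ier == 1 and max(abs(np.asarray(moments(sol)))) < 1e-6:
        return float(sol[0]), float(abs(sol[1]))
    return _truncnorm_location(target_mean, target_sd, lo, hi), target_sd


def _draw_scores(rng: np.random.Generator, n: int, mean: float, sd: float,
                 lo: int, hi: int) -> np.ndarray:
    mu, sig = _truncnorm_params(mean, sd, lo - 0.5, hi + 0.5)
    a, b = (lo - 0.5 - mu) / sig, (hi + 0.5 - mu) / sig
    raw = truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)
    return np.clip(np.rint(raw), lo, hi).astype(int)


# --- diagnoses ------------------------------------------------------------


def _conditional_base_logit(target: float, partners: list[tuple[float, float]]) -> float:
    """Base log-odds for a diagnosis drawn conditionally on independent partner
    diagnoses with given (prevalence, odds multiplier), preserving the target
    marginal prevalence."""
    if not partners:
        return float(logit(target))

    probs = np.array([p for p, _ in partners])
    logms = np.log([m for _, m in partners])

    def marginal(l0: float) -> float:
        total = 0.0
        for combo in itertools.product([0, 1], repeat=len(partners)):
            z = np.array(combo)
            w = float(np.prod(np.where(z == 1, probs, 1 - probs)))
            total += w * float(expit(l0 + float(z @ logms)))
        return total

    return brentq(lambda l0: marginal(l0) - target, -30, 30, xtol=1e-10)


def _draw_diagnoses(rng: np.random.Generator, n: int, params: SimulationParams) -> list[frozenset[str]]:
    prev = params.diagnosis_prevalence
    if not prev:
        return [frozenset()] * n
    # diagnoses appearing second in a comorbidity pair are drawn conditionally
    dependents = {b for (_, b) in params.comorbidity}
    independents = [d for d in prev if d not in dependents]
    draws: dict[str, np.ndarray] = {}
    for d in independents:
        draws[d] = rng.random(n) < prev[d]
    for d in sorted(dependents):
        partners = [(a, m) for (a, b), m in params.comorbidity.items() if b == d]
        l0 = _conditional_base_logit(prev[d], [(prev[a], m) for a, m in partners])
        eta = np.full(n, l0)
        for a, m in partners:
            eta = eta + np.where(draws[a], np.log(m), 0.0)
        draws[d] = rng.random(n) < expit(eta)
    return [
        frozenset(d for d in prev if draws[d][i]) for i in range(n)
    ]


# --- outcome generation ---------------------------------------------------


def _event_probabilities(params: SimulationParams, outcome: str, score: np.ndarray) -> dict[float, np.ndarray]:
    """Cumulative event probability per horizon; enforced nondecreasing in horizon."""
    probs: dict[float, np.ndarray] = {}
    prev = np.zeros_like(score, dtype=float)
    for h in params.horizons(outcome):
        m = params.outcome_models[(outcome, h)]
        p = expit(m.b0 + m.b1 * score)
        p = np.maximum(p, prev)
        probs[h] = p
        prev = p
    return probs


def generate_cohort(params: SimulationParams, spec: InstrumentSpec | None = None) -> list[CohortRecord]:
    """Generate a seeded synthetic cohort.

    Sex is Bernoulli(prop_male); total scores come from the sex-specific
    truncated-normal model rounded to integers; per outcome a single latent
    uniform is compared against the cumulative horizon probabilities, so
    shorter-horizon events are nested within longer ones.  Event times are
    uniform within the horizon slice in which the event falls.  If the
    configured outcomes include both 'violent' and 'general', the latent
    uniform is shared so violent events are a subset of general events.
    Events occurring after the subject's follow-up end are not observed.
    """
    params.validate()
    spec = spec or default_spec()
    rng = np.random.default_rng([params.seed, STREAM_COHORT])
    n = params.n_subjects

    male = rng.random(n) < params.prop_male
    sexes = np.where(male, "male", "female")
    scores = np.empty(n, dtype=int)
    for sex in ("male", "female"):
        idx = np.flatnonzero(sexes == sex)
        if idx.size == 0:
            continue
        if sex not in params.score_model:
            raise ConfigError(f"no score model for sex {sex!r}")
        mean, sd = params.score_model[sex]
        scores[idx] = _draw_scores(rng, idx.size, mean, sd, spec.min_total, spec.max_total)

    diagnoses = _draw_diagnoses(rng, n, params)
    lo, hi = params.follow_up_range
    follow_up = rng.uniform(lo, hi, size=n)

    outcomes = params.outcomes()
    shared = {"violent", "general"}.issubset(outcomes)
    u_shared = rng.random(n)
    frac_shared = rng.random(n)
    # sharing both the latent uniform and the within-slice time fraction keeps
    # violent events a subset of general events even under follow-up censoring
    latent = {o: (u_shared if (shared and o in ("violent", "general")) else rng.random(n)) for o in outcomes}
    time_frac = {o: (frac_shared if (shared and o in ("violent", "general")) else rng.random(n)) for o in outcomes}

    events: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    for o in outcomes:
        probs = _event_probabilities(params, o, scores)
        horizons = sorted(probs)
        t = np.full(n, np.nan)
        prev_h, prev_p = 0.0, np.zeros(n)
        for h in horizons:
            p = probs[h]
            in_slice = (latent[o] >= prev_p) & (latent[o] < p)
            t[in_slice] = prev_h + time_frac[o][in_slice] * (h - prev_h)
            prev_h, prev_p = h, p
        observed = ~np.isnan(t) & (t <= follow_up)
        times[o] = np.where(observed, t, np.nan)
        events[o] = observed

    records = []
    width = len(str(n))
    for i in range(n):
        score = int(scores[i])
        records.append(
            CohortRecord(
                subject_id=f"S{i + 1:0{width}d}",
                sex=str(sexes[i]),
                diagnoses=diagnoses[i],
                total_score=score,
                bin=assign_bin(score, spec),
                follow_up_years=float(follow_up[i]),
                events={o: bool(events[o][i]) for o in outcomes},
                event_times={o: (float(times[o][i]) if events[o][i] else None) for o in outcomes},
            )
        )
    return records


# --- item sheets and raters ----------------------------------------------


def _decompose_total(rng: np.random.Generator, total: int, spec: InstrumentSpec) -> dict[str, int]:
    """Random item weights consistent with the total: start from a random
    profile, then walk single items toward the target one step at a time."""
    weights = {it.name: int(rng.choice(it.allowed_weights)) for it in spec.items}
    diff = total - sum(weights.values())
    for _ in range(100_000):
        if diff == 0:
            break
        direction = 1 if diff > 0 else -1
        movable = []
        for it in spec.items:
            allowed = it.allowed_weights
            pos = allowed.index(weights[it.name])
            if 0 <= pos + direction < len(allowed):
                step = allowed[pos + direction] - allowed[pos]
                if abs(step) <= abs(diff):
                    movable.append((it.name, step, pos))
        if not movable:  # overshoot-free step unavailable; allow any step toward target
            for it in spec.items:
                allowed = it.allowed_weights
                pos = allowed.index(weights[it.name])
                if 0 <= pos + direction < len(allowed):
                    movable.append((it.name, allowed[pos + direction] - allowed[pos], pos))
        name, step, _ = movable[rng.integers(len(movable))]
        it = spec.item(name)
        pos = it.allowed_weights.index(weights[name])
        weights[name] = it.allowed_weights[pos + direction]
        diff = total - sum(weights.values())
    else:
        raise ConfigError(f"could not decompose total {total} into item weights")
    return weights


def generate_item_sheets(
    cohort: Sequence[CohortRecord],
    spec: InstrumentSpec,
    params: SimulationParams,
) -> list[ScoreSheet]:
    """Score sheets whose pre-omission totals equal each record's total.

    Each item is independently omitted with ``missing_item_rate``, capped at
    ``spec.max_missing`` omissions per sheet (excess omissions are restored in
    random order).
    """
    params.validate()
    rng = np.random.default_rng([params.seed, STREAM_SHEETS])
    sheets = []
    for rec in cohort:
        weights = _decompose_total(rng, rec.total_score, spec)
        rec.item_weights = dict(weights)
        masked: dict[str, int | None] = dict(weights)
        if params.missing_item_rate > 0:
            omit = [n for n in spec.item_names if rng.random() < params.missing_item_rate]
            if len(omit) > spec.max_missing:
                omit = list(rng.permutation(omit)[: spec.max_missing])
            for n in omit:
                masked[n] = None
        sheets.append(ScoreSheet(subject_id=rec.subject_id, item_weights=masked))
    return sheets


def generate_rater_pair(
    sheets: Sequence[ScoreSheet],
    spec: InstrumentSpec,
    params: SimulationParams,
) -> list[ScoreSheet]:
    """Second-rater re-scores: each scored item is kept with probability
    ``1 - rater_disagreement``, else perturbed within the item's allowed set.

    Kernels: 'adjacent' moves up to ``rater_magnitude`` positions within the
    allowed set (direction and size uniform, excluding zero); 'uniform'
    redraws uniformly from the full allowed set.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, STREAM_RATER])
    out = []
    for sheet in sheets:
        weights: dict[str, int | None] = {}
        for it in spec.items:
            w = sheet.item_weights.get(it.name)
            if w is None or rng.random() >= params.rater_disagreement:
                weights[it.name] = w
                continue
            allowed = it.allowed_weights
            if params.rater_kernel == "uniform" or len(allowed) == 1:
                weights[it.name] = int(rng.choice(allowed))
            else:
                pos = allowed.index(int(w))
                steps = [
                    s
                    for s in range(-params.rater_magnitude, params.rater_magnitude + 1)
                    if s != 0 and 0 <= pos + s < len(allowed)
                ]
                weights[it.name] = int(allowed[pos + steps[rng.integers(len(steps))]]) if steps else int(w)
        out.append(ScoreSheet(subject_id=sheet.subject_id, item_weights=weights))
    return out


# --- cohort I/O -----------------------------------------------------------


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    outcomes = sorted(cohort[0].events) if cohort else []
    rows = []
    for rec in cohort:
        row: dict = {
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "diagnoses": ";".join(sorted(rec.diagnoses)),
            "total_score": rec.total_score,
            "bin": rec.bin,
            "follow_up_years": rec.follow_up_years,
        }
        for o in outcomes:
            row[f"{o}_event"] = int(rec.events[o])
            t = rec.event_times[o]
            row[f"{o}_time_years"] = "" if t is None else t
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[CohortRecord]:
    outcomes = sorted(c[: -len("_event")] for c in df.columns if c.endswith("_event"))
    records = []
    for _, row in df.iterrows():
        events = {o: bool(int(row[f"{o}_event"])) for o in outcomes}
        times: dict[str, float | None] = {}
        for o in outcomes:
            v = row.get(f"{o}_time_years")
            times[o] = None if (v is None or v == "" or pd.isna(v)) else float(v)
        diag = row.get("diagnoses", "")
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                sex=str(row["sex"]),
                diagnoses=frozenset(d for d in str(diag).split(";") if d) if pd.notna(diag) else frozenset(),
                total_score=int(row["total_score"]),
                bin=int(row["bin"]),
                follow_up_years=float(row["follow_up_years"]),
                events=events,
                event_times=times,
            )
        )
    return records


def write_cohort(cohort: Sequence[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})
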