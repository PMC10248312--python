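"""Actuarial instrument representation and scoring.

An instrument is a fixed set of integer-weighted static items.  Item weights
are summed to a total score, which is mapped onto one of nine ordered risk
bins.  Incomplete score sheets (up to ``max_missing`` omitted items) are
prorated by adding the mean weight of the scored items once per missing item.

The shipped default instrument has twelve items with published weight ranges
summing to a total-score range of -34 to +46, and the nine-bin layout used by
the normative comparison tables (bin 1 at or below -25, bin 9 at 28 and up).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

__all__ = [
    "InstrumentError",
    "ItemDef",
    "InstrumentSpec",
    "ScoreSheet",
    "TotalScore",
    "ProratedScore",
    "default_spec",
    "total_score",
    "prorate",
    "assign_bin",
    "round_half_away",
    "load_spec",
    "save_spec",
    "read_sheets",
    "write_sheets",
]


class InstrumentError(ValueError):
    """Raised on invalid instrument specs, score sheets, or out-of-range totals."""


@dataclass(frozen=True)
class ItemDef:
    """One static item with its finite set of permissible integer weights."""

    name: str
    allowed_weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.allowed_weights:
            raise InstrumentError(f"item {self.name!r} has an empty weight set")
        object.__setattr__(self, "allowed_weights", tuple(sorted(set(int(w) for w in self.allowed_weights))))

    @property
    def min_weight(self) -> int:
        return self.allowed_weights[0]

    @property
    def max_weight(self) -> int:
        return self.allowed_weights[-1]


@dataclass(frozen=True)
class InstrumentSpec:
    """Item definitions plus the bin layout defined on total scores.

    ``bin_edges`` are inclusive integer intervals ``(lo, hi)``, ordered,
    disjoint, and jointly covering ``[min_total, max_total]``.
    """

    items: tuple[ItemDef, ...]
    bin_edges: tuple[tuple[int, int], ...]
    max_missing: int = 4
    name: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "bin_edges", tuple((int(a), int(b)) for a, b in self.bin_edges))
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise InstrumentError("duplicate item names")
        if self.max_missing < 0 or self.max_missing >= len(self.items):
            raise InstrumentError("max_missing must be in [0, n_items)")
        lo, hi = self.min_total, self.max_total
        prev_hi = lo - 1
        for a, b in self.bin_edges:
            if a > b:
                raise InstrumentError(f"bin interval ({a}, {b}) is empty")
            if a != prev_hi + 1:
                raise InstrumentError("bin intervals must be ordered, disjoint and contiguous over the score range")
            prev_hi = b
        if self.bin_edges[0][0] != lo or self.bin_edges[-1][1] != hi:
            raise InstrumentError(f"bins must cover [{lo}, {hi}]")

    @property
    def min_total(self) -> int:
        return sum(it.min_weight for it in self.items)

    @property
    def max_total(self) -> int:
        return sum(it.max_weight for it in self.items)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    def item(self, name: str) -> ItemDef:
        for it in self.items:
            if it.name == name:
                return it
        raise InstrumentError(f"unknown item {name!r}")


@dataclass
class ScoreSheet:
    """Per-subject item weights; ``None`` marks an omitted item."""

    subject_id: str
    item_weights: dict[str, int | None] = field(default_factory=dict)

    def missing_items(self, spec: InstrumentSpec) -> list[str]:
        return [n for n in spec.item_names if self.item_weights.get(n) is None]


class TotalScore(NamedTuple):
    total: int
    n_missing: int


class ProratedScore(NamedTuple):
    unprorated: int
    prorated: float
    adjustment: float
    n_missing: int


# --- default instrument ---------------------------------------------------

_DEFAULT_ITEM_RANGES: tuple[tuple[str, int, int], ...] = (
    ("lived_with_parents_to_16", -2, 2),
    ("elementary_school_maladjustment", -3, 4),
    ("alcohol_drug_problems", -2, 4),
    ("marital_status_at_index", -1, 1),
    ("nonviolent_criminal_history", -3, 5),
    ("conditional_release_failure", -2, 4),
    ("age_at_index", -7, 2),
    ("violent_criminal_history", -2, 4),
    ("prior_correctional_admissions", -2, 6),
    ("conduct_disorder_before_15", -2, 5),
    ("sex_offending_history", -2, 3),
    ("antisociality", -6, 6),
)

_DEFAULT_BIN_EDGES: tuple[tuple[int, int], ...] = (
    (-34, -25),
    (-24, -19),
    (-18, -14),
    (-13, -8),
    (-7, 5),
    (6, 12),
    (13, 18),
    (19, 27),
    (28, 46),
)


def default_spec() -> InstrumentSpec:
    """The shipped twelve-item spec with all integers in each printed range."""
    items = tuple(
        ItemDef(name, tuple(range(lo, hi + 1))) for name, lo, hi in _DEFAULT_ITEM_RANGES
    )
    return InstrumentSpec(items=items, bin_edges=_DEFAULT_BIN_EDGES, max_missing=4)


# --- scoring --------------------------------------------------------------


def _validate_sheet(sheet: ScoreSheet, spec: InstrumentSpec) -> None:
    for it in spec.items:
        w = sheet.item_weights.get(it.name)
        if w is None:
            continue
        if int(w) not in it.allowed_weights:
            raise InstrumentError(
                f"weight {w} not allowed for item {it.name!r} "
                f"(allowed: {it.min_weight}..{it.max_weight})"
            )


def total_score(sheet: ScoreSheet, spec: InstrumentSpec) -> TotalScore:
    """Sum of non-missing item weights plus the count of omitted items.

    Raises
    ------
    InstrumentError
        If a weight lies outside its item's allowed set, or no item is scored.
    """
    _validate_sheet(sheet, spec)
    scored = [int(sheet.item_weights[n]) for n in spec.item_names if sheet.item_weights.get(n) is not None]
    if not scored:
        raise InstrumentError(f"sheet {sheet.subject_id!r}: no items scored")
    n_missing = len(spec.items) - len(scored)
    return TotalScore(total=sum(scored), n_missing=n_missing)


def prorate(sheet: ScoreSheet, spec: InstrumentSpec) -> ProratedScore:
    """Prorated total for a sheet with up to ``spec.max_missing`` omitted items.

    The adjustment adds the mean weight of the scored items once per missing
    item: ``prorated = unprorated + n_missing * mean(scored weights)``.  With
    nothing missing the unprorated total is returned unchanged.
    """
    unprorated, n_missing = total_score(sheet, spec)
    if n_missing == 0:
        return ProratedScore(unprorated, float(unprorated), 0.0, 0)
    if n_missing > spec.max_missing:
        raise InstrumentError(
            f"sheet {sheet.subject_id!r}: too many omitted items to prorate "
            f"({n_missing} > {spec.max_missing})"
        )
    n_scored = len(spec.items) - n_missing
    adjustment = n_missing * unprorated / n_scored
    return ProratedScore(unprorated, unprorated + adjustment, adjustment, n_missing)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def assign_bin(total: float, spec: InstrumentSpec) -> int:
    """Bin number (1-based) whose interval contains ``total``.

    Fractional (prorated) totals are rounded half-away-from-zero before lookup.
    """
    t = round_half_away(float(total))
    for i, (lo, hi) in enumerate(spec.bin_edges, start=1):
        if lo <= t <= hi:
            return i
    raise InstrumentError(
        f"total {total} outside instrument range [{spec.min_total}, {spec.max_total}]"
    )


# --- persistence ----------------------------------------------------------


def _spec_to_dict(spec: InstrumentSpec) -> dict:
    return {
        "name": spec.name,
        "max_missing": spec.max_missing,
        "bins": [list(e) for e in spec.bin_edges],
        "items": [
            {"name": it.name, "weights": list(it.allowed_weights)} for it in spec.items
        ],
    }


def _spec_from_dict(d: Mapping) -> InstrumentSpec:
    items = []
    for entry in d["items"]:
        if "weights" in entry:
            weights = tuple(int(w) for w in entry["weights"])
        elif "range" in entry:
            lo, hi = entry["range"]
            weights = tuple(range(int(lo), int(hi) + 1))
        else:
            raise InstrumentError(f"item {entry.get('name')!r}: need 'weights' or 'range'")
        items.append(ItemDef(entry["name"], weights))
    return InstrumentSpec(
        items=tuple(items),
        bin_edges=tuple((int(a), int(b)) for a, b in d["bins"]),
        max_missing=int(d.get("max_missing", 4)),
        name=str(d.get("name", "custom")),
    )


def save_spec(spec: InstrumentSpec, path: str | Path) -> None:
    path = Path(path)
    payload = _spec_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_spec(path: str | Path) -> InstrumentSpec:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _spec_from_dict(d)


# --- score-sheet I/O ------------------------------------------------------


def read_sheets(path: str | Path, spec: InstrumentSpec) -> list[ScoreSheet]:
    """Read sheets from delimited text: a subject_id column plus one column
    per item; empty fields or 'NA' mark omitted items."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = [n for n in spec.item_names if n not in df.columns]
    if missing_cols:
        raise InstrumentError(f"sheet file lacks item columns: {missing_cols}")
    sheets = []
    for _, row in df.iterrows():
        weights: dict[str, int | None] = {}
        for n in spec.item_names:
            v = row[n]
            weights[n] = None if pd.isna(v) else int(v)
        sheets.append(ScoreSheet(subject_id=str(row["subject_id"]), item_weights=weights))
    return sheets


def write_sheets(sheets: Iterable[ScoreSheet], spec: InstrumentSpec, path: str | Path) -> None:
    rows = []
    for s in sheets:
        row: dict = {"subject_id": s.subject_id}
        for n in spec.item_names:
            w = s.item_weights.get(n)
            row[n] = "" if w is None else int(w)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
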