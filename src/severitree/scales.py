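"""Instrument definitions, scoring, and tripartite severity stratification.

The two screening instruments handled here are the 7-item Generalized Anxiety
Disorder scale (GAD-7) and the 9-item Patient Health Questionnaire (PHQ-9).
Every item is answered on a 0 ("not at all") to 3 ("nearly every day") scale,
so totals range over 0..21 (GAD-7) and 0..27 (PHQ-9).  Totals are mapped to
three ordered severity classes:

* ``minimal_mild`` — total below 10 on either scale;
* ``moderate``     — 10..14 on GAD-7, 10..19 on PHQ-9 (reported as
  "moderate or moderately severe" for the PHQ-9);
* ``severe``       — >= 15 on GAD-7, >= 20 on PHQ-9.

The cutoffs live in :class:`ScaleSpec` rather than in code so alternative
stratifications (e.g. the common single cutoff of 10) remain configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MINIMAL_MILD",
    "MODERATE",
    "SEVERE",
    "SEVERITY_LEVELS",
    "severity_rank",
    "ScaleSpec",
    "GAD7",
    "PHQ9",
    "get_scale",
    "total_score",
    "stratify",
    "validate_table",
    "ValidationReport",
    "DEMOGRAPHIC_COLUMNS",
    "AGE_COLUMN",
]

MINIMAL_MILD = "minimal_mild"
MODERATE = "moderate"
SEVERE = "severe"

#: Severity levels in increasing order of severity.
SEVERITY_LEVELS: tuple[str, str, str] = (MINIMAL_MILD, MODERATE, SEVERE)

_SEVERITY_RANK = {level: i for i, level in enumerate(SEVERITY_LEVELS)}

#: Categorical covariates recognised in cohort tables, in canonical order.
DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("sex", "skin_color", "education", "age_group")
AGE_COLUMN = "age"


def severity_rank(level: str) -> int:
    """Position of *level* in the minimal_mild < moderate < severe ordering."""
    try:
        return _SEVERITY_RANK[level]
    except KeyError:
        raise ValueError(f"unknown severity level: {level!r}") from None


@dataclass(frozen=True)
class ScaleSpec:
    """Definition of one instrument: item layout plus severity cutoffs.

    Parameters
    ----------
    name
        Instrument identifier, e.g. ``"GAD7"``.
    n_items
        Number of items (7 or 9 for the built-in scales).
    cutoff_moderate, cutoff_severe
        Total-score thresholds: totals below ``cutoff_moderate`` are
        minimal/mild, totals in ``[cutoff_moderate, cutoff_severe)`` are
        moderate, totals at or above ``cutoff_severe`` are severe.
    item_prefix
        Prefix used for 1-based item column names (``GAD1``..``GAD7``).
    middle_display
        Display string for the middle class in rendered reports.
    """

    name: str
    n_items: int
    cutoff_moderate: int
    cutoff_severe: int
    item_prefix: str
    item_min: int = 0
    item_max: int = 3
    middle_display: str = "Moderate"

    def __post_init__(self) -> None:
        if not (0 <= self.item_min < self.item_max):
            raise ValueError("require 0 <= item_min < item_max")
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if not (self.cutoff_moderate < self.cutoff_severe <= self.max_total):
            raise ValueError("require cutoff_moderate < cutoff_severe <= n_items * item_max")

    @property
    def max_total(self) -> int:
        """Maximum attainable total score (21 for GAD-7, 27 for PHQ-9)."""
        return self.n_items * self.item_max

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(f"{self.item_prefix}{i}" for i in range(1, self.n_items + 1))

    def item_index(self, name: str) -> int | None:
        """1-based index of an item column name, or None for non-items."""
        if name.startswith(self.item_prefix):
            suffix = name[len(self.item_prefix):]
            if suffix.isdigit() and 1 <= int(suffix) <= self.n_items:
                return int(suffix)
        return None

    def display_label(self, level: str) -> str:
        """Human-readable class label used in rendered reports."""
        if level == MINIMAL_MILD:
            return "Minimal or mild"
        if level == MODERATE:
            return self.middle_display
        if level == SEVERE:
            return "Severe"
        raise ValueError(f"unknown severity level: {level!r}")


GAD7 = ScaleSpec(name="GAD7", n_items=7, cutoff_moderate=10, cutoff_severe=15,
                 item_prefix="GAD")
PHQ9 = ScaleSpec(name="PHQ9", n_items=9, cutoff_moderate=10, cutoff_severe=20,
                 item_prefix="PHQ", middle_display="Moderate or moderately severe")

_SCALES = {"gad7": GAD7, "phq9": PHQ9}


def get_scale(name: str | ScaleSpec) -> ScaleSpec:
    """Resolve a scale by (case-insensitive) name; passes specs through."""
    if isinstance(name, ScaleSpec):
        return name
    try:
        return _SCALES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown scale {name!r}; expected one of {sorted(_SCALES)}") from None


def total_score(responses: Sequence[int] | np.ndarray, spec: ScaleSpec) -> int:
    """Sum one respondent's item vector after validating length and range."""
    arr = np.asarray(responses)
    if arr.shape != (spec.n_items,):
        raise ValueError(
            f"{spec.name} expects {spec.n_items} item responses, got shape {arr.shape}"
        )
    for i, value in enumerate(arr, start=1):
        v = float(value)
        if not v.is_integer() or not (spec.item_min <= v <= spec.item_max):
            raise ValueError(
                f"item {spec.item_prefix}{i}: value {value!r} outside integer range "
                f"[{spec.item_min}, {spec.item_max}]"
            )
    return int(arr.sum())


def stratify(total: int, spec: ScaleSpec) -> str:
    """Map a total score to its severity class."""
    t = float(total)
    if not t.is_integer() or not (0 <= t <= spec.max_total):
        raise ValueError(f"total {total!r} outside attainable range [0, {spec.max_total}]")
    if t < spec.cutoff_moderate:
        return MINIMAL_MILD
    if t < spec.cutoff_severe:
        return MODERATE
    return SEVERE


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`: how many rows survived screening."""

    n_input: int
    n_retained: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_retained


def validate_table(raw: pd.DataFrame, spec: ScaleSpec) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate a respondent-level item table and attach derived columns.

    Rows with any missing, non-integer, or out-of-range item response are
    dropped (incomplete records are excluded, mirroring the study design) and
    counted in the returned :class:`ValidationReport`.  The retained table
    gains ``total`` and ``severity`` columns; re-validating a validated table
    is a no-op apart from recomputing those two columns.

    Raises
    ------
    ValueError
        If any of the scale's item columns is absent entirely.
    """
    missing = [c for c in spec.item_names if c not in raw.columns]
    if missing:
        raise ValueError(f"missing item columns for {spec.name}: {missing}")

    items = raw[list(spec.item_names)].apply(pd.to_numeric, errors="coerce")
    in_range = items.ge(spec.item_min) & items.le(spec.item_max)
    is_integer = items.eq(items.round())
    keep = (items.notna() & in_range & is_integer).all(axis=1)

    out = raw.loc[keep].copy()
    out[list(spec.item_names)] = items.loc[keep].astype(np.int64)
    out["total"] = out[list(spec.item_names)].sum(axis=1).astype(np.int64)
    bins_moderate = out["total"] >= spec.cutoff_moderate
    bins_severe = out["total"] >= spec.cutoff_severe
    out["severity"] = np.where(bins_severe, SEVERE, np.where(bins_moderate, MODERATE, MINIMAL_MILD))
    out = out.reset_index(drop=True)
    return out, ValidationReport(n_input=len(raw), n_retained=len(out))
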