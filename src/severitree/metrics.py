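"""One-vs-rest screening metrics for mined rules.

A rule is evaluated as a binary screener for its predicted severity class:
rows matching every condition are flagged positive, rows of the target class
are the true positives.  Point metrics (accuracy, sensitivity, specificity,
precision, F1) come from the confusion counts; AUC is the trapezoidal area
under the ROC curve, identical to the Mann-Whitney concordance probability
with ties counted one half.

Two AUC scoring modes are provided.  ``"binary"`` scores each row with the
0/1 rule indicator, whose AUC collapses to (sensitivity + specificity) / 2.
``"tree_probability"`` (the default) scores rows with the repetition tree's
predicted probability of the rule's class, giving a graded, class-level
curve — in particular both middle-class rules of one tree share a single
AUC, matching how per-rule AUCs well above the binary closed form arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mining import RepArtifact, Rule
from .scales import MINIMAL_MILD, MODERATE, SEVERE, SEVERITY_LEVELS, ScaleSpec, get_scale

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RuleSummary",
    "EvaluationReport",
    "apply_rule",
    "confusion",
    "point_metrics",
    "roc_auc",
    "evaluate_rules_over_reps",
    "external_validate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricSet:
    """Screening metrics in [0, 1].  ``precision_defined`` is False when the
    rule flagged nothing (TP + FP = 0); precision and F1 are then reported
    as 0 rather than dropped so that means stay computable."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None = None
    precision_defined: bool = True

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def apply_rule(rule: Rule, table: pd.DataFrame) -> np.ndarray:
    """Boolean vector: True where every condition of ``rule`` holds."""
    out = np.ones(len(table), dtype=bool)
    for cond in rule.conditions:
        if cond.feature not in table.columns:
            raise ValueError(f"table is missing item/column {cond.feature!r}")
        out &= cond.matches(table[cond.feature].to_numpy())
    return out


def confusion(predicted_positive: np.ndarray, true_labels: np.ndarray,
              target_class: str) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``target_class`` as positive."""
    pred = np.asarray(predicted_positive, dtype=bool)
    truth = np.asarray(true_labels)
    if pred.shape != truth.shape:
        raise ValueError("predictions and labels have different lengths")
    pos = truth == target_class
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)), fn=int(np.sum(~pred & pos)))


def point_metrics(cm: ConfusionCounts) -> MetricSet:
    """Accuracy / sensitivity / specificity / precision / F1 from counts."""
    if cm.n == 0:
        raise ValueError("cannot compute metrics on zero observations")
    accuracy = (cm.tp + cm.tn) / cm.n
    sensitivity = cm.tp / cm.n_positive if cm.n_positive else 0.0
    specificity = cm.tn / cm.n_negative if cm.n_negative else 0.0
    flagged = cm.tp + cm.fp
    if flagged:
        precision = cm.tp / flagged
        defined = True
    else:
        precision = 0.0
        defined = False
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    return MetricSet(accuracy, sensitivity, specificity, precision, f1,
                     precision_defined=defined)


def roc_auc(scores: Sequence[float] | np.ndarray,
            positives: Sequence[bool] | np.ndarray) -> float:
    """Trapezoidal area under the ROC curve traced over all thresholds.

    Computed in count space with a single final division, so it agrees with
    the Mann-Whitney probability P(score+ > score-) + P(score+ = score-)/2
    to the last bit; ties contribute half via the trapezoids.
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    if s.shape != pos.shape:
        raise ValueError("scores and labels have different lengths")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    # per unique score level: positive / negative counts
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.append(boundary, s_sorted.size - 1)
    cum_tp = np.cumsum(pos_sorted)[ends]
    cum_fp = (ends + 1) - cum_tp
    tp = np.concatenate(([0], cum_tp))
    fp = np.concatenate(([0], cum_fp))
    area2 = np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1]))  # 2 x area in counts
    return float(area2 / (2 * n_pos * n_neg))


@dataclass
class RuleSummary:
    """Mean (SD) of each metric for one rule across repetitions."""

    rule: Rule
    repetitions: int | None          # catalog repetition count, if known
    n_used: int
    n_skipped: int
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class EvaluationReport:
    scale: str
    auc_mode: str
    rows: list[RuleSummary] = field(default_factory=list)

    def for_class(self, level: str) -> list[RuleSummary]:
        return [r for r in self.rows if r.rule.predicted == level]

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "auc_mode": self.auc_mode,
            "rows": [
                {"rule": r.rule.to_dict(), "repetitions": r.repetitions,
                 "n_used": r.n_used, "n_skipped": r.n_skipped,
                 "mean": r.mean, "sd": r.sd}
                for r in self.rows
            ],
        }


def _rule_metrics(rule: Rule, art: RepArtifact, auc_mode: str) -> MetricSet | None:
    y = art.test_y
    if not np.any(y == rule.predicted):
        return None  # held-out set lacks the target class: skip this repetition
    flag = apply_rule(rule, art.test_X)
    ms = point_metrics(confusion(flag, y, rule.predicted))
    if auc_mode == "binary":
        scores = flag.astype(float)
    elif auc_mode == "tree_probability":
        if art.clf is None:
            raise ValueError("tree_probability AUC requires fitted trees in the artifacts")
        class_idx = int(np.flatnonzero(art.clf.classes_ == rule.predicted)[0])
        scores = art.clf.predict_proba(art.test_X[list(art.feature_set)])[:, class_idx]
    else:
        raise ValueError(f"unknown auc_mode {auc_mode!r}")
    if np.all(y == rule.predicted):
        ms.auc = None
    else:
        ms.auc = roc_auc(scores, y == rule.predicted)
    return ms


def evaluate_rules_over_reps(
    rules: Iterable[Rule] | Mapping[str, Sequence[tuple[Rule, int]]],
    artifacts: Sequence[RepArtifact],
    *,
    auc_mode: str = "tree_probability",
    scale: ScaleSpec | str | None = None,
) -> EvaluationReport:
    """Evaluate selected rules on every repetition's held-out partition.

    ``rules`` may be a flat rule iterable or the mapping returned by
    :meth:`RuleCatalog.top_rules` (whose catalog counts are carried into the
    report).  Each rule is scored on each repetition's test set whether or
    not that repetition's tree contained it; repetitions whose test set lacks
    the rule's class are skipped and counted.
    """
    counted: list[tuple[Rule, int | None]] = []
    if isinstance(rules, Mapping):
        for level in SEVERITY_LEVELS:
            for rule, count in rules.get(level, []):
                counted.append((rule, count))
    else:
        counted = [(r, None) for r in rules]
    if not counted:
        raise ValueError("no rules to evaluate")
    if not artifacts:
        raise ValueError("no repetition artifacts supplied")
    scale_name = get_scale(scale).name if scale is not None else counted[0][0].scale

    report = EvaluationReport(scale=scale_name, auc_mode=auc_mode)
    for rule, count in counted:
        per_rep: list[MetricSet] = []
        skipped = 0
        for art in artifacts:
            ms = _rule_metrics(rule, art, auc_mode)
            if ms is None:
                skipped += 1
            else:
                per_rep.append(ms)
        if not per_rep:
            report.rows.append(RuleSummary(rule, count, 0, skipped, {}, {}))
            continue
        mean: dict[str, float] = {}
        sd: dict[str, float] = {}
        for name in METRIC_NAMES:
            vals = np.array([getattr(m, name) for m in per_rep
                             if getattr(m, name) is not None], dtype=float)
            if vals.size == 0:
                continue
            mean[name] = float(vals.mean())
            sd[name] = float(vals.std())  # population SD: one repetition -> 0
        report.rows.append(RuleSummary(rule, count, len(per_rep), skipped, mean, sd))
    return report


def external_validate(
    rules: Iterable[Rule] | Mapping[str, Sequence[tuple[Rule, int]]],
    table: pd.DataFrame,
    scale: ScaleSpec | str,
    *,
    y_column: str = "severity",
) -> dict[str, dict]:
    """Apply a frozen rule set unchanged to a new validated cohort.

    Single-pass metrics (no resampling) per rule, plus per-class metrics
    where the middle class is screened by the union (OR) of its rules.  AUC
    uses the binary rule indicator — the only score available without a tree.

    Raises
    ------
    ValueError
        If the rules' scale does not match ``scale`` or the table misses the
        scale's item columns.
    """
    spec = get_scale(scale)
    flat: list[Rule] = []
    if isinstance(rules, Mapping):
        for level in SEVERITY_LEVELS:
            flat.extend(r for r, _ in rules.get(level, []))
    else:
        flat = list(rules)
    if not flat:
        raise ValueError("no rules to validate")
    for rule in flat:
        if rule.scale != spec.name:
            raise ValueError(f"rule scale {rule.scale} does not match table scale {spec.name}")
    missing = [c for c in spec.item_names if c not in table.columns]
    if missing:
        raise ValueError(f"validation table is missing item columns: {missing}")
    y = table[y_column].to_numpy()

    def metrics_for(flag: np.ndarray, level: str) -> MetricSet:
        ms = point_metrics(confusion(flag, y, level))
        pos = y == level
        if pos.any() and (~pos).any():
            ms.auc = roc_auc(flag.astype(float), pos)
        return ms

    per_rule = {rule.text: metrics_for(apply_rule(rule, table), rule.predicted)
                for rule in flat}
    per_class: dict[str, MetricSet] = {}
    for level in SEVERITY_LEVELS:
        of_level = [r for r in flat if r.predicted == level]
        if not of_level:
            continue
        union = np.zeros(len(table), dtype=bool)
        for rule in of_level:
            union |= apply_rule(rule, table)
        per_class[level] = metrics_for(union, level)
    return {"per_rule": per_rule, "per_class": per_class}
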