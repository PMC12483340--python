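"""Ensemble rule mining: repeated 70/30 resampling, tree fitting, and
root-to-leaf rule extraction into a repetition-counted catalog.

Each repetition draws a without-replacement 70/30 train/test partition
(Monte-Carlo cross-validation), tunes the tree depth on the training side by
stratified 10-fold CV, grows a CART tree, and turns every root-to-leaf path
into a canonical conjunction of item conditions predicting that leaf's
severity class.  Counting how often each canonical rule recurs across the
whole ensemble — over feature sets and over the (minsplit, minbucket)
hyperparameter grid — is the stability criterion that singles out the short,
reproducible screening rules.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .scales import (MINIMAL_MILD, MODERATE, SEVERE, SEVERITY_LEVELS,
                     DEMOGRAPHIC_COLUMNS, ScaleSpec, get_scale, severity_rank)
from .tree import CartClassifier, SplitCandidate, TreeNode

__all__ = [
    "Condition",
    "Rule",
    "RuleCatalog",
    "RepArtifact",
    "RuleMiner",
    "split_train_test",
    "extract_rules",
    "canonicalize",
    "top_rules",
    "DEFAULT_FEATURE_SETS",
    "DEFAULT_HP_GRID",
]

#: items-only plus one demographic variable at a time
DEFAULT_FEATURE_SETS: tuple[str, ...] = (
    "items", "items+sex", "items+skin_color", "items+education", "items+age_group")

#: the 3 x 3 (minsplit, minbucket) grid explored for robustness
DEFAULT_HP_GRID: tuple[tuple[int, int], ...] = tuple(
    (ms, mb) for ms in (500, 1000, 2000) for mb in (500, 1000, 2000))

#: training size at which the hyperparameter grid values are quoted
REFERENCE_TRAIN_N = 14410


@dataclass(frozen=True)
class Condition:
    """One conjunct of a rule: an item interval or a category subset.

    Ordinal conditions keep an inclusive integer interval ``[lo, hi]`` inside
    the item's 0..3 range; a full-range interval is meaningless and rejected.
    Nominal conditions keep a sorted category subset.
    """

    feature: str
    lo: int | None = None
    hi: int | None = None
    categories: tuple[str, ...] | None = None
    item_min: int = 0
    item_max: int = 3

    @property
    def is_ordinal(self) -> bool:
        return self.categories is None

    def __post_init__(self) -> None:
        if self.is_ordinal:
            if self.lo is None or self.hi is None:
                raise ValueError("ordinal condition requires lo and hi")
            if not (self.item_min <= self.lo <= self.hi <= self.item_max):
                raise ValueError(
                    f"empty or out-of-range interval [{self.lo}, {self.hi}] for {self.feature}")
            if self.lo == self.item_min and self.hi == self.item_max:
                raise ValueError(f"full-range condition on {self.feature} must be dropped")
        else:
            if not self.categories:
                raise ValueError(f"empty category set for {self.feature}")

    def render(self) -> str:
        if not self.is_ordinal:
            return f"{self.feature}∈{{{','.join(self.categories)}}}"
        lo, hi = int(self.lo), int(self.hi)
        if lo == hi:
            return f"{self.feature}={lo}"
        if lo == self.item_min:
            return f"{self.feature}<{hi + 1}"
        if hi == self.item_max:
            return f"{self.feature}≥{lo}"
        return f"{lo}≤{self.feature}<{hi + 1}"

    def matches(self, values: np.ndarray) -> np.ndarray:
        if self.is_ordinal:
            v = np.asarray(values, dtype=float)
            return (v >= self.lo) & (v <= self.hi)
        return np.isin(np.asarray(values, dtype=object).astype(str), list(self.categories))


@dataclass(frozen=True)
class Rule:
    """A canonical conjunction of conditions predicting one severity class."""

    scale: str
    predicted: str
    conditions: tuple[Condition, ...]

    @property
    def text(self) -> str:
        if not self.conditions:
            return "(root)"
        return " and ".join(c.render() for c in self.conditions)

    def to_dict(self) -> dict:
        conds = []
        for c in self.conditions:
            if c.is_ordinal:
                conds.append({"feature": c.feature, "lo": c.lo, "hi": c.hi})
            else:
                conds.append({"feature": c.feature, "categories": list(c.categories)})
        return {"scale": self.scale, "class": self.predicted,
                "rule": self.text, "conditions": conds}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Rule":
        spec = get_scale(d["scale"])
        conds = []
        for c in d["conditions"]:
            if "categories" in c:
                conds.append(Condition(c["feature"], categories=tuple(c["categories"])))
            else:
                conds.append(Condition(c["feature"], lo=int(c["lo"]), hi=int(c["hi"])))
        return canonicalize(cls(spec.name, d["class"], tuple(conds)))


def _condition_sort_key(cond: Condition, spec: ScaleSpec):
    idx = spec.item_index(cond.feature)
    if idx is not None:
        return (0, idx, cond.feature)
    try:
        demo_pos = DEMOGRAPHIC_COLUMNS.index(cond.feature)
    except ValueError:
        demo_pos = len(DEMOGRAPHIC_COLUMNS)
    return (1, demo_pos, cond.feature)


def canonicalize(rule: Rule) -> Rule:
    """Return the canonical form: per-feature conditions intersected,
    full-range conditions dropped, conditions sorted (items in scale order,
    then demographics).  Idempotent; logically identical paths render to
    string-identical rules.

    Raises
    ------
    ValueError
        If a feature's conditions intersect to an empty interval or empty
        category set (a contradictory path, which fitted trees never emit).
    """
    spec = get_scale(rule.scale)
    by_feature: dict[str, Condition] = {}
    order: list[str] = []
    for cond in rule.conditions:
        if cond.feature not in by_feature:
            by_feature[cond.feature] = cond
            order.append(cond.feature)
            continue
        prev = by_feature[cond.feature]
        if prev.is_ordinal != cond.is_ordinal:
            raise ValueError(f"mixed ordinal/nominal conditions on {cond.feature}")
        if cond.is_ordinal:
            lo, hi = max(prev.lo, cond.lo), min(prev.hi, cond.hi)
            if lo > hi:
                raise ValueError(f"contradictory interval for {cond.feature}")
            by_feature[cond.feature] = Condition(cond.feature, lo=lo, hi=hi,
                                                 item_min=cond.item_min,
                                                 item_max=cond.item_max)
        else:
            inter = tuple(sorted(set(prev.categories) & set(cond.categories)))
            if not inter:
                raise ValueError(f"contradictory category subset for {cond.feature}")
            by_feature[cond.feature] = Condition(cond.feature, categories=inter)
    kept = sorted(by_feature.values(), key=lambda c: _condition_sort_key(c, spec))
    kept = [Condition(c.feature, lo=c.lo, hi=c.hi,
                      categories=tuple(sorted(c.categories)) if c.categories else None,
                      item_min=c.item_min, item_max=c.item_max)
            for c in kept]
    return Rule(rule.scale, rule.predicted, tuple(kept))


def extract_rules(clf: CartClassifier, scale: ScaleSpec | str) -> list[tuple[Rule, np.ndarray]]:
    """One canonical rule per leaf: the conjunction of the split conditions on
    the root-to-leaf path, predicting the leaf's majority class.  A
    single-leaf tree yields one empty-condition rule.  Returns
    ``(rule, leaf class counts)`` pairs in left-to-right leaf order."""
    spec = get_scale(scale)
    cat_lookup = {f.name: f.categories for f in clf._feats if f.kind == "nominal"}
    out: list[tuple[Rule, np.ndarray]] = []

    def walk(node: TreeNode, conds: tuple[Condition, ...]) -> None:
        if node.is_leaf:
            predicted = str(clf.classes_[node.majority_code])
            rule = canonicalize(Rule(spec.name, predicted, conds))
            out.append((rule, node.counts.copy()))
            return
        s: SplitCandidate = node.split
        if s.kind == "ordinal":
            t = float(s.threshold)
            left = Condition(s.feature, lo=spec.item_min, hi=int(np.floor(t)))
            right = Condition(s.feature, lo=int(np.ceil(t)), hi=spec.item_max)
        else:
            all_cats = cat_lookup[s.feature]
            left = Condition(s.feature, categories=tuple(sorted(s.left_categories)))
            rest = tuple(sorted(set(all_cats) - set(s.left_categories)))
            right = Condition(s.feature, categories=rest)
        walk(node.left, conds + (left,))
        walk(node.right, conds + (right,))

    walk(clf.tree_, ())
    return out


def _rule_sort_key(item: tuple[Rule, int]):
    rule, count = item
    return (-count, len(rule.conditions), rule.text)


class RuleCatalog:
    """Repetition counts of canonical rules across a tree ensemble."""

    def __init__(self, scale: ScaleSpec | str):
        self.scale = get_scale(scale)
        self.counts: Counter[Rule] = Counter()
        self.provenance: dict[Rule, list[tuple]] = defaultdict(list)
        self.n_trees = 0

    def add_tree(self, rules: Iterable[Rule], provenance: tuple) -> None:
        self.n_trees += 1
        for rule in rules:
            self.counts[rule] += 1
            self.provenance[rule].append(provenance)

    @property
    def total_repetitions(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def by_class(self, level: str) -> list[tuple[Rule, int]]:
        items = [(r, c) for r, c in self.counts.items() if r.predicted == level]
        return sorted(items, key=_rule_sort_key)

    def top_rules(self, k_per_class: Mapping[str, int] | None = None
                  ) -> dict[str, list[tuple[Rule, int]]]:
        """Most repeated rules per class, sorted by count (ties: fewer
        conditions first, then lexicographic).  Defaults to one rule for the
        extreme classes and two for the middle class."""
        if self.n_distinct == 0:
            raise ValueError("catalog is empty")
        k = {MINIMAL_MILD: 1, MODERATE: 2, SEVERE: 1}
        if k_per_class:
            k.update(k_per_class)
        out: dict[str, list[tuple[Rule, int]]] = {}
        for level in SEVERITY_LEVELS:
            ranked = self.by_class(level)
            if not ranked:
                warnings.warn(f"no mined rules predict class {level!r}")
            out[level] = ranked[: k.get(level, 1)]
        return out

    def to_dict(self) -> dict:
        rules = [{**r.to_dict(), "repetitions": c,
                  "provenance": [list(p) for p in self.provenance[r]]}
                 for r, c in sorted(self.counts.items(), key=_rule_sort_key)]
        return {"scale": self.scale.name, "n_trees": self.n_trees,
                "n_distinct": self.n_distinct,
                "total_repetitions": self.total_repetitions, "rules": rules}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleCatalog":
        cat = cls(d["scale"])
        cat.n_trees = int(d["n_trees"])
        for entry in d["rules"]:
            rule = Rule.from_dict(entry)
            cat.counts[rule] = int(entry["repetitions"])
            cat.provenance[rule] = [tuple(p) for p in entry.get("provenance", [])]
        return cat


def top_rules(catalog: RuleCatalog, k_per_class: Mapping[str, int] | None = None):
    return catalog.top_rules(k_per_class)


def split_train_test(table: pd.DataFrame, train_fraction: float = 0.7,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive without-replacement train/test partition.

    The training size is round-half-up(n * fraction), computed with exact
    rational arithmetic: binary-float rounding of e.g. 20585 * 0.7 + 0.5
    would otherwise land one row short of the intended 14,410.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot partition an empty table")
    frac = Fraction(str(float(train_fraction)))
    if not (0 < frac < 1):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_train = int(frac * n + Fraction(1, 2))
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {train_fraction} leaves an empty partition at n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (table.iloc[perm[:n_train]].reset_index(drop=True),
            table.iloc[perm[n_train:]].reset_index(drop=True))


@dataclass
class RepArtifact:
    """Everything needed to re-evaluate one repetition: the fitted tree and
    that repetition's held-out partition."""

    feature_set: tuple[str, ...]
    hp: tuple[int, int]
    rep: int
    seed_key: tuple[int, ...]
    clf: CartClassifier | None
    test_X: pd.DataFrame
    test_y: np.ndarray


def _resolve_feature_set(fs, spec: ScaleSpec) -> tuple[str, ...]:
    if isinstance(fs, str):
        if fs == "items":
            return spec.item_names
        if fs.startswith("items+"):
            extra = fs[len("items+"):]
            if extra not in DEMOGRAPHIC_COLUMNS:
                raise ValueError(f"unknown demographic {extra!r} in feature set {fs!r}")
            return spec.item_names + (extra,)
        raise ValueError(f"unknown feature set {fs!r}")
    return tuple(fs)


class RuleMiner(BaseEstimator):
    """Mine stable decision-tree rules by repeated resampling.

    ``fit(X, y)`` runs the full design — every feature set crossed with every
    (minsplit, minbucket) configuration, ``reps`` repetitions each — and
    accumulates canonical leaf rules into :attr:`catalog_`.

    Parameters
    ----------
    scale : ScaleSpec or str
        Instrument whose items appear in ``X``.
    feature_sets : sequence
        Named sets (``"items"``, ``"items+sex"``, ...) or explicit column
        tuples.  Default: items only plus one demographic at a time.
    hp_grid : sequence of (minsplit, minbucket)
        Hyperparameter configurations, quoted at the reference training size
        of 14,410 rows and rescaled proportionally when ``scale_to_n``.
    reps : int
        Repetitions per (feature set, configuration) cell.
    train_fraction : float
        Training share of each without-replacement partition.
    random_state : int
        Base seed; every repetition derives its own seed from
        (base, feature-set index, config index, repetition index).

    Attributes
    ----------
    catalog_ : RuleCatalog
    artifacts_ : list of RepArtifact
    n_trees_ : int
    skipped_ : list of (feature set, hp) cells skipped as infeasible.
    """

    def __init__(self, *, scale="gad7",
                 feature_sets: Sequence = ("items",),
                 hp_grid: Sequence[tuple[int, int]] = ((500, 500),),
                 reps: int = 1000, train_fraction: float = 0.7,
                 max_depth_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
                 cv: int = 10, scale_to_n: bool = True,
                 reference_n: int = REFERENCE_TRAIN_N,
                 keep_artifacts: bool = True, random_state: int = 0):
        self.scale = scale
        self.feature_sets = feature_sets
        self.hp_grid = hp_grid
        self.reps = reps
        self.train_fraction = train_fraction
        self.max_depth_grid = max_depth_grid
        self.cv = cv
        self.scale_to_n = scale_to_n
        self.reference_n = reference_n
        self.keep_artifacts = keep_artifacts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "RuleMiner":
        spec = get_scale(self.scale)
        if y is None:
            if "severity" not in X.columns:
                raise ValueError("pass y explicitly or include a 'severity' column in X")
            y = X["severity"].to_numpy()
        y = np.asarray(y)
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

        base = int(self.random_state)
        catalog = RuleCatalog(spec)
        artifacts: list[RepArtifact] = []
        skipped: list[tuple] = []

        feature_sets = [_resolve_feature_set(fs, spec) for fs in self.feature_sets]
        table = X.copy()
        table["__y__"] = y

        for fs_i, cols in enumerate(feature_sets):
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"feature set {cols} misses columns {missing}")
            for cfg_i, (minsplit, minbucket) in enumerate(self.hp_grid):
                # feasibility depends only on the (deterministic) training size
                n_train = int(Fraction(str(float(self.train_fraction))) * len(table)
                              + Fraction(1, 2))
                eff_ms = max(2, round(minsplit * n_train / self.reference_n)) \
                    if self.scale_to_n else minsplit
                if eff_ms > n_train:
                    warnings.warn(
                        f"skipping infeasible configuration minsplit={minsplit}, "
                        f"minbucket={minbucket} (effective minsplit {eff_ms} exceeds "
                        f"training size {n_train})")
                    skipped.append((cols, (minsplit, minbucket)))
                    continue
                for rep in range(self.reps):
                    seed_key = (base, fs_i, cfg_i, rep)
                    ss = np.random.SeedSequence(seed_key)
                    rng = np.random.default_rng(ss)
                    train, test = split_train_test(table, self.train_fraction, rng)
                    tree_seed = int(ss.generate_state(1)[0] % (2 ** 31))
                    clf = CartClassifier(
                        minsplit=minsplit, minbucket=minbucket, max_depth=None,
                        max_depth_grid=self.max_depth_grid, cv=self.cv,
                        scale_to_n=self.scale_to_n, reference_n=self.reference_n,
                        nominal_features=[c for c in cols if c in DEMOGRAPHIC_COLUMNS],
                        random_state=tree_seed,
                    ).fit(train[list(cols)], train["__y__"].to_numpy())
                    rules = [r for r, _ in extract_rules(clf, spec)]
                    catalog.add_tree(rules, (fs_i, cfg_i, rep))
                    if self.keep_artifacts:
                        artifacts.append(RepArtifact(
                            feature_set=cols, hp=(minsplit, minbucket), rep=rep,
                            seed_key=seed_key, clf=clf,
                            test_X=test.drop(columns="__y__"),
                            test_y=test["__y__"].to_numpy()))

        self.catalog_ = catalog
        self.artifacts_ = artifacts
        self.n_trees_ = catalog.n_trees
        self.skipped_ = skipped
        return self

    def top_rules(self, k_per_class: Mapping[str, int] | None = None):
        return self.catalog_.top_rules(k_per_class)
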