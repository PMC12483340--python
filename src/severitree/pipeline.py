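"""Pipeline orchestration: generate -> mine -> evaluate -> validate -> report.

A :class:`PipelineConfig` (usually loaded from a YAML file) describes one run:
which instrument, where the cohort comes from (a generator configuration or a
CSV path — exactly one of the two), the mining design, and evaluation
options.  Every random draw descends from the single recorded base seed, so
re-running an identical configuration reproduces byte-identical rule catalogs
and report tables.

Two profiles bundle sensible defaults: ``demo`` (n=4,000, one feature set,
one hyperparameter configuration, 50 repetitions — minutes on one CPU) and
``replication`` (n=20,585, five feature sets, the full 3x3 grid, 1,000
repetitions — the full-scale design).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GeneratorConfig, generate_cohort
from .metrics import (METRIC_NAMES, EvaluationReport, evaluate_rules_over_reps,
                      external_validate)
from .mining import (DEFAULT_FEATURE_SETS, DEFAULT_HP_GRID, Rule, RuleCatalog,
                     RuleMiner)
from .scales import SEVERITY_LEVELS, ScaleSpec, get_scale, validate_table

__all__ = [
    "PipelineConfig",
    "PROFILES",
    "run_pipeline",
    "PipelineResult",
    "write_rules",
    "read_rules",
    "render_report",
    "render_tree",
    "load_config",
]

PROFILES: dict[str, dict] = {
    "demo": {
        "n": 4000,
        "feature_sets": ["items"],
        "hp_grid": [[2000, 2000]],
        "reps": 50,
    },
    "replication": {
        "n": 20585,
        "feature_sets": list(DEFAULT_FEATURE_SETS),
        "hp_grid": [list(hp) for hp in DEFAULT_HP_GRID],
        "reps": 1000,
    },
}


@dataclass
class PipelineConfig:
    """Structured description of one pipeline run."""

    scale: str = "gad7"
    seed: int = 0
    cohort_path: str | None = None      # exactly one of cohort_path /
    generator: dict = field(default_factory=dict)  # generator kwargs is active
    feature_sets: list = field(default_factory=lambda: ["items"])
    hp_grid: list = field(default_factory=lambda: [[500, 500]])
    reps: int = 50
    train_fraction: float = 0.7
    scale_to_n: bool = True
    auc_mode: str = "tree_probability"
    k_per_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_path is not None and self.generator:
            raise ValueError("provide either a cohort path or a generator config, not both")

    @classmethod
    def from_profile(cls, profile: str, *, scale: str = "gad7", seed: int = 0,
                     **overrides) -> "PipelineConfig":
        base = dict(PROFILES[profile])
        n = base.pop("n")
        cfg = dict(scale=scale, seed=seed, generator={"n": n}, **base)
        cfg.update(overrides)
        return cls(**cfg)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        profile = d.pop("profile", None)
        if profile:
            base = dict(PROFILES[profile])
            n = base.pop("n")
            merged = dict(generator={"n": n}, **base)
            merged.update(d)
            d = merged
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _load_cohort(config: PipelineConfig, spec: ScaleSpec) -> tuple[pd.DataFrame, bool]:
    if config.cohort_path is not None:
        raw = pd.read_csv(config.cohort_path)
        table, _ = validate_table(raw, spec)
        return table, False
    gen_kwargs = dict(config.generator)
    gen_kwargs.setdefault("seed", config.seed)
    gen = GeneratorConfig(scale=spec, **gen_kwargs)
    return generate_cohort(gen), True


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame
    catalog: RuleCatalog
    top: dict
    report: EvaluationReport
    paths: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline and (optionally) write all artifacts.

    Writes, under ``out_dir``: the cohort CSV (when generated), the rule
    catalog, the top-rule set, the rendered TSV report plus its structured
    JSON form, and a run-metadata record carrying the seeds and design.
    """
    spec = get_scale(config.scale)
    cohort, generated = _load_cohort(config, spec)

    miner = RuleMiner(
        scale=spec, feature_sets=tuple(config.feature_sets),
        hp_grid=tuple(tuple(hp) for hp in config.hp_grid),
        reps=config.reps, train_fraction=config.train_fraction,
        scale_to_n=config.scale_to_n, random_state=config.seed,
    ).fit(cohort.drop(columns=["total", "severity"]), cohort["severity"].to_numpy())

    top = miner.top_rules(config.k_per_class or None)
    report = evaluate_rules_over_reps(top, miner.artifacts_,
                                      auc_mode=config.auc_mode, scale=spec)

    result = PipelineResult(config=config, cohort=cohort, catalog=miner.catalog_,
                            top=top, report=report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if generated:
            result.paths["cohort"] = out / "cohort.csv"
            cohort.to_csv(result.paths["cohort"], index=False)
        result.paths["catalog"] = out / "catalog.json"
        _dump_json(miner.catalog_.to_dict(), result.paths["catalog"])
        result.paths["rules"] = out / "top_rules.json"
        write_rules(top, result.paths["rules"])
        result.paths["report_tsv"] = out / "report.tsv"
        result.paths["report_tsv"].write_text(render_report(report), encoding="utf-8")
        result.paths["report_json"] = out / "report.json"
        _dump_json(report.to_dict(), result.paths["report_json"])
        result.paths["metadata"] = out / "run_metadata.json"
        _dump_json({
            "severitree_version": __version__,
            "config": dataclasses.asdict(config),
            "n_trees": miner.n_trees_,
            "n_distinct_rules": miner.catalog_.n_distinct,
            "total_repetitions": miner.catalog_.total_repetitions,
            "skipped_configurations": [list(map(list, s)) for s in miner.skipped_],
        }, result.paths["metadata"])
    return result


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# ---------------------------------------------------------------- rule files

def write_rules(rules, path: str | Path) -> None:
    """Serialise a rule set (mapping class -> [(rule, count)] or iterable of
    rules) with both structured conditions and the rendered rule string."""
    entries = []
    if isinstance(rules, Mapping):
        for level in SEVERITY_LEVELS:
            for rule, count in rules.get(level, []):
                entries.append({**rule.to_dict(), "repetitions": count})
    else:
        entries = [r.to_dict() for r in rules]
    scale = entries[0]["scale"] if entries else None
    _dump_json({"scale": scale, "rules": entries}, Path(path))


def read_rules(path: str | Path) -> list[Rule]:
    """Read a rule file back into canonical :class:`Rule` objects.

    Raises a parse error naming the offending rule entry for malformed or
    contradictory condition sets.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed rule file {path} at line {exc.lineno}: {exc.msg}") from exc
    rules = []
    for i, entry in enumerate(doc.get("rules", [])):
        try:
            rules.append(Rule.from_dict(entry))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"invalid rule entry {i} in {path}: {exc}") from exc
    return rules


# ------------------------------------------------------------------ rendering

def _fmt(mean: float | None, sd: float | None) -> str:
    if mean is None:
        return "—"
    return f"{mean:.3f} ({sd:.3f})"


def render_report(report: EvaluationReport) -> str:
    """Render an evaluation report as a TSV table, one row per (class, rule),
    metrics formatted as ``mean (SD)`` to three decimals.  Pure: identical
    reports render to identical bytes."""
    spec = get_scale(report.scale)
    header = ["Class", "Rule", "Repetition", "Accuracy", "Sensitivity",
              "Specificity", "Precision", "F-score", "AUC"]
    lines = ["\t".join(header)]
    for level in SEVERITY_LEVELS:
        for row in report.for_class(level):
            cells = [spec.display_label(level), row.rule.text,
                     str(row.repetitions if row.repetitions is not None else row.n_used)]
            for name in METRIC_NAMES:
                cells.append(_fmt(row.mean.get(name), row.sd.get(name)))
            lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_tree(clf) -> str:
    """Indented text summary of a fitted tree (class counts per node)."""
    lines: list[str] = []

    def walk(node, indent: str, label: str) -> None:
        counts = "/".join(str(int(c)) for c in node.counts)
        head = f"{indent}{label}n={node.n} [{counts}]"
        if node.is_leaf:
            lines.append(f"{head} -> {clf.classes_[node.majority_code]}")
        else:
            lines.append(f"{head} split: {node.split.describe()}")
            walk(node.left, indent + "  ", "yes: ")
            walk(node.right, indent + "  ", "no:  ")

    walk(clf.tree_, "", "")
    return "\n".join(lines) + "\n"


def render_external(results: Mapping[str, dict], spec: ScaleSpec) -> str:
    """TSV rendering of an external-validation result."""
    header = ["Level", "Rule", "Accuracy", "Sensitivity", "Specificity",
              "Precision", "F-score", "AUC"]
    lines = ["\t".join(header)]
    for text, ms in results["per_rule"].items():
        cells = ["rule", text] + [
            f"{getattr(ms, name):.3f}" if getattr(ms, name) is not None else "—"
            for name in METRIC_NAMES]
        lines.append("\t".join(cells))
    for level, ms in results["per_class"].items():
        cells = ["class", spec.display_label(level)] + [
            f"{getattr(ms, name):.3f}" if getattr(ms, name) is not None else "—"
            for name in METRIC_NAMES]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
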