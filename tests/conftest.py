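"""Shared fixtures.

The heavier fixtures are session-scoped: the ten seeded demo-profile mining
runs (n=4,000 cohorts, one feature set, one hyperparameter configuration,
50 repetitions each) back several acceptance checks — rule recovery, the
extreme-vs-middle accuracy ordering — and are computed once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from severitree.cohort import GeneratorConfig, generate_cohort
from severitree.metrics import evaluate_rules_over_reps
from severitree.mining import RuleMiner
from severitree.scales import GAD7

DEMO_HP = (2000, 2000)
DEMO_N = 4000
DEMO_REPS = 50


def run_demo(seed: int, *, reps: int = DEMO_REPS, feature_sets=("items",),
             hp=DEMO_HP, generator_kwargs=None) -> RuleMiner:
    """One demo-profile mining run on a freshly generated GAD-7 cohort."""
    cfg = GeneratorConfig(n=DEMO_N, seed=1000 + seed, **(generator_kwargs or {}))
    cohort = generate_cohort(cfg)
    return RuleMiner(
        scale="gad7", feature_sets=feature_sets, hp_grid=(hp,), reps=reps,
        random_state=seed,
    ).fit(cohort.drop(columns=["total", "severity"]), cohort["severity"].to_numpy())


@pytest.fixture(scope="session")
def demo_runs() -> list[RuleMiner]:
    """Ten seeded demo-profile mining runs (items only, hub defaults)."""
    return [run_demo(seed) for seed in range(10)]


@pytest.fixture(scope="session")
def demo_reports(demo_runs):
    """Evaluation reports of the top rules of each demo run."""
    return [evaluate_rules_over_reps(m.top_rules(), m.artifacts_) for m in demo_runs]


@pytest.fixture(scope="session")
def small_gad_cohort() -> pd.DataFrame:
    return generate_cohort(GeneratorConfig(n=2000, seed=99))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
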