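"""Shared fixtures: small cohorts for unit tests, one full-scale evaluation
run (drifted study conditions) and one null-cohort run, both session-scoped
because they back several end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

import ctgrisk as cg
from ctgrisk.evaluate import EvalConfig, run_evaluation
from ctgrisk.features import featurize_cohort
from ctgrisk.forest import ForestConfig
from ctgrisk.simulate import CohortConfig, null_cohort_config, simulate_cohort


def short_cohort_config(size: int, seed: int) -> CohortConfig:
    """Study-condition parameters but 1-3 h records, for fast unit tests."""
    config = CohortConfig(size=size, seed=seed)
    from dataclasses import replace

    config.params = {
        g: replace(p, duration_range_s=(3600.0, 10800.0))
        for g, p in config.params.items()
    }
    return config


@pytest.fixture(scope="session")
def small_cohort() -> list[cg.LaborRecord]:
    """50 short simulated records with the default group mix."""
    return simulate_cohort(short_cohort_config(size=50, seed=202))


@pytest.fixture(scope="session")
def drifted_evaluation():
    """The study conditions at desk scale: 2,000 subjects, 10 train/test
    iterations, 300-tree forests. Backs calibration, separation and
    trajectory checks."""
    records = simulate_cohort(CohortConfig(size=2000, seed=20230))
    table = featurize_cohort(records)
    config = EvalConfig(forest=ForestConfig(n_trees=300))
    results, summary = run_evaluation(
        records, config, n_iterations=10, seed=77, feature_table=table
    )
    return {"records": records, "table": table, "results": results, "summary": summary}


@pytest.fixture(scope="session")
def trajectory_run():
    """One full-cohort training pass (5,000 subjects) for the out-of-bag
    epoch-probability trajectories; the median-pHIE figure is computed from
    a single training set, so this uses one forest, not repeated splits.
    The larger cohort gives the rare HIE group (~46 subjects) enough mass
    for stable per-epoch medians."""
    import pandas as pd

    from ctgrisk.events import PATHOLOGICAL_GROUPS
    from ctgrisk.forest import oob_probabilities, train_forest

    records = simulate_cohort(CohortConfig(size=5000, seed=31415))
    table = featurize_cohort(records)
    valid = table[table["valid"]]
    y = valid["group"].isin(PATHOLOGICAL_GROUPS).to_numpy(dtype=int)
    model = train_forest(valid, y, ForestConfig(n_trees=300), rng=5)
    oob = oob_probabilities(model, valid, y)
    oob_table = pd.DataFrame(
        {
            "group": valid["group"].to_numpy(),
            "epoch_index": valid["epoch_index"].to_numpy(),
            "phie": oob,
        }
    )
    return {"records": records, "oob_table": oob_table}


@pytest.fixture(scope="session")
def null_evaluation():
    """Negative control: identical generative parameters in all groups."""
    records = simulate_cohort(null_cohort_config(size=1000, seed=555))
    config = EvalConfig(forest=ForestConfig(n_trees=200))
    results, _ = run_evaluation(records, config, n_iterations=3, seed=99)
    return {"records": records, "results": results}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
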