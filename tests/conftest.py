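"""Shared fixtures: tiny hand-built cohorts and session-scoped synthetic runs.

Seed convention mirrors the pipeline: cohort generation uses the base seed,
the train/validation split uses base+1, the forest fit base+2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hccsurv.cohort import BINARY_COLUMNS, CATEGORICAL_LEVELS, COLUMNS, Cohort
from hccsurv.hazard import RSFConfig, km_profile, rsf_profile, true_profile
from hccsurv.synthetic import default_generator_config, generate_cohort, split_cohort

BASE_SEED = 0


def make_cohort(times, events, seed: int = 5, label: str = "tiny") -> Cohort:
    """Cohort with given PFS times/event flags and random covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (t, e) in enumerate(zip(times, events)):
        row = {"patient_id": f"P{i:04d}", "pfs_months": float(t), "event": bool(e)}
        for b in BINARY_COLUMNS:
            row[b] = bool(rng.integers(2))
        for col, levels in CATEGORICAL_LEVELS.items():
            row[col] = levels[int(rng.integers(len(levels)))]
        rows.append(row)
    return Cohort(pd.DataFrame(rows)[COLUMNS], label=label)


@pytest.fixture(scope="session")
def cohort546():
    return generate_cohort(default_generator_config(n=546, seed=BASE_SEED))


@pytest.fixture(scope="session")
def train_valid(cohort546):
    return split_cohort(cohort546, 0.70, seed=BASE_SEED + 1)


@pytest.fixture(scope="session")
def rsf_train_profile(train_valid):
    train, _ = train_valid
    return rsf_profile(train, RSFConfig(n_trees=1000, seed=BASE_SEED + 2), 36)


@pytest.fixture(scope="session")
def cohort50k_null():
    """n=50,000, covariate effects all zero: every patient on the baseline hazard."""
    cfg = default_generator_config(
        n=50_000, seed=BASE_SEED, covariate_log_effects={}
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort50k_default():
    """n=50,000 under the full default config (nonzero synthetic effects)."""
    return generate_cohort(default_generator_config(n=50_000, seed=BASE_SEED))


@pytest.fixture(scope="session")
def true_default():
    return true_profile(default_generator_config())


@pytest.fixture(scope="session")
def true_null():
    return true_profile(default_generator_config(covariate_log_effects={}))
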