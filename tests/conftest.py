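"""Shared fixtures: cohorts and fitted forests reused across test modules.

Expensive objects (fitted forests) are session-scoped; small forests are
used wherever the semantics, not the operating characteristics, are under
test.
"""

import numpy as np
import pandas as pd
import pytest

from siristrat import (
    HazardSpec,
    SurvivalForest,
    generate_cohort,
    split_cohort,
)

NULL_HAZARDS = HazardSpec(log_hr_siri_high=0.0, log_hr_kps_low=0.0, log_hr_ever_smoker=0.0)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study condition: n=600 with planted threshold effects."""
    return generate_cohort(n=600, seed=11)


@pytest.fixture(scope="session")
def default_split(default_cohort):
    part = split_cohort(default_cohort, seed=11)
    train = default_cohort[part == "train_validation"].reset_index(drop=True)
    test = default_cohort[part == "test"].reset_index(drop=True)
    return train, test


@pytest.fixture(scope="session")
def small_forest(default_split):
    """A 200-tree forest: enough for semantics and split-rule tests."""
    train, _ = default_split
    return SurvivalForest(n_trees=200, random_state=11).fit(train)


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(hz=NULL_HAZARDS, n=600, seed=42)
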