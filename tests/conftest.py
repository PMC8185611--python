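"""Shared fixtures: small default cohort, a large calibration cohort with a
known incremental societal cost, and the default unit-cost table."""

import numpy as np
import pytest

from trialcea import CohortParams, UnitCostTable, generate_cohort
from trialcea.cohort import DEFAULT_COST_MEANS
from trialcea.inference import regression_impute
from trialcea.scenarios import add_outcome_columns, build_analysis_frame


def calibration_means() -> dict:
    """Component means whose expected societal difference (including the fixed
    299 EUR intervention price) is exactly -900 EUR."""
    means = dict(DEFAULT_COST_MEANS)
    means["absenteeism"] = (1005.0, 1014.0)
    return means


TRUE_DELTA_COST = -900.0
TRUE_DELTA_QALY = 0.019


@pytest.fixture(scope="session")
def table() -> UnitCostTable:
    return UnitCostTable()


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort: 2 x 64, default remission/cost/dropout structure."""
    return generate_cohort(CohortParams(seed=42))


@pytest.fixture(scope="session")
def no_dropout_cohort():
    return generate_cohort(CohortParams(seed=42, dropout_rate=0.0))


@pytest.fixture(scope="session")
def recovery_frame():
    """Large imputed analysis frame from the calibration cohort (n=10 000 per
    arm, known incremental cost -900 EUR and QALY gain 0.019)."""
    params = CohortParams(n_per_arm=10_000, cost_component_means=calibration_means(), seed=11)
    frame = build_analysis_frame(generate_cohort(params))
    frame = regression_impute(frame)
    return add_outcome_columns(frame, "societal")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
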