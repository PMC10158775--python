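import dataclasses

import pytest

from ctmrd.background import build_background_from_frame
from ctmrd.pipeline import analyze_cohort, build_records, call_cohort
from ctmrd.simulate import SimulationConfig, as_bundle, simulate_cohort_data

SMALL = dataclasses.replace(
    SimulationConfig(),
    n_patients=40,
    n_panel_sites=100,
    n_healthy=120,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort shared across tests (seed fixed)."""
    return simulate_cohort_data(SMALL, seed=11)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return build_background_from_frame(small_cohort.healthy_panel, min_panel_depth=1000)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return as_bundle(small_cohort)


@pytest.fixture(scope="session")
def small_calls(small_bundle, small_cohort, small_model):
    return call_cohort(small_bundle, small_cohort.chip_db, small_model)


@pytest.fixture(scope="session")
def small_records(small_bundle, small_calls):
    return build_records(small_bundle, small_calls)


@pytest.fixture(scope="session")
def small_result(small_records):
    return analyze_cohort(small_records)
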