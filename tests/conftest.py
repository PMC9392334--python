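import numpy as np
import pytest

from clusterni import TrialScenario, build_analysis_dataset, generate_trial, validity_filter


@pytest.fixture(scope="session")
def default_records():
    """One realisation of the default (trial-like) scenario."""
    return generate_trial(TrialScenario(seed=123))


@pytest.fixture(scope="session")
def default_dataset(default_records):
    valid, excluded = validity_filter(default_records)
    return build_analysis_dataset(valid, exclusion_log=excluded)


@pytest.fixture(scope="session")
def small_scenario():
    """Quick-to-fit scenario: 6 schools/arm, no missingness or invalids."""
    return TrialScenario(
        n_schools_per_arm=6,
        teachers_per_school=4,
        baseline_sd=35.0,
        followup_gain=0.0,  # keeps natural totals clear of the validity bound
        missing_rate_baseline=0.0,
        missing_rate_followup=0.0,
        invalid_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    valid, excluded = validity_filter(generate_trial(small_scenario))
    return build_analysis_dataset(valid, exclusion_log=excluded)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
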