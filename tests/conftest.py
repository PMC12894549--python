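import numpy as np
import pytest

from miburden import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_projection_inputs,
    run_projection,
)


@pytest.fixture(scope="session")
def cohort_50k():
    """The reference synthetic cohort: 50,000 people, default study-like mix."""
    return generate_cohort(SyntheticCohortConfig(n_people=50_000, seed=0))


@pytest.fixture(scope="session")
def cohort_small():
    """A fast cohort for interface-level tests."""
    return generate_cohort(SyntheticCohortConfig(n_people=2_000, seed=11))


@pytest.fixture(scope="session")
def inputs_default():
    return generate_projection_inputs(seed=1)


@pytest.fixture(scope="session")
def base_trace(inputs_default):
    return run_projection(inputs_default)


def weighted_mean(values, weights):
    return float(np.average(np.asarray(values, float), weights=np.asarray(weights, float)))
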