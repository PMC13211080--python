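import numpy as np
import pytest

from segt2star import CohortDesign, EchoProtocol, generate_segmental_cohort


@pytest.fixture(scope="session")
def protocol() -> EchoProtocol:
    return EchoProtocol()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 50-subject, sex- and age-balanced synthetic cohort."""
    return generate_segmental_cohort(CohortDesign(seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """A 5000-subject cohort for population-level recovery checks."""
    return generate_segmental_cohort(CohortDesign(n_subjects=5000, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
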