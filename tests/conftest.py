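import numpy as np
import pytest

from tnbcqsp.cohort import PopulationSpec, generate_cohort
from tnbcqsp.params import PatientParameters
from tnbcqsp.trial import run_trial


@pytest.fixture(scope="session")
def default_patient():
    return PatientParameters()


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-patient cohort shared by the cohort/trial/biomarker tests."""
    return generate_cohort(PopulationSpec(n_patients=16, seed=3))


@pytest.fixture(scope="session")
def small_trial(small_cohort):
    """A short (9-assessment) trial on the shared cohort."""
    return run_trial(small_cohort, duration_days=567, n_boot=200, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
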