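import pytest
from hypothesis import settings as hyp_settings, HealthCheck

from vaflow.solver import SolverSettings
from vaflow.synthetic import canonical_patient
from vaflow.pipeline import personalize_patient

hyp_settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def coarse_settings():
    """Throughput-oriented solver settings used across the suite."""
    return SolverSettings(dt=5e-3, n_cycles=25)


@pytest.fixture(scope="session")
def clean_patient(coarse_settings):
    return canonical_patient("clean", solver_settings=coarse_settings)


@pytest.fixture(scope="session")
def mild_patient(coarse_settings):
    return canonical_patient("mild", solver_settings=coarse_settings)


@pytest.fixture(scope="session")
def severe_patient(coarse_settings):
    return canonical_patient("severe", solver_settings=coarse_settings)


@pytest.fixture(scope="session")
def clean_case(clean_patient, coarse_settings):
    return personalize_patient(clean_patient, settings=coarse_settings)
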