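import numpy as np
import pytest
from hypothesis import settings

from mirdkit import CohortConfig, PatientMeta, Phantom, gen_cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def patient() -> PatientMeta:
    return PatientMeta("P01", weight_kg=70.0, injected_activity_MBq=200.0)


@pytest.fixture(scope="session")
def toy_phantom() -> Phantom:
    return Phantom(
        name="toy",
        sex="male",
        total_mass_kg=70.0,
        organ_masses_g={"liver": 1000.0, "kidneys": 500.0, "spleen": 100.0},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 42)."""
    return gen_cohort(CohortConfig(), seed=42)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return gen_cohort(
        CohortConfig(noise_cv=0.0, organ_jitter_cv=0.0), seed=7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
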