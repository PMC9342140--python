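import pytest
from hypothesis import HealthCheck, settings

from cvrmodel import IndividualProfile, derive_basic_cardio

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fit_profile() -> IndividualProfile:
    """Reference fit male: 25 yr, 75 kg, 175 cm, V̇o2max 4.0 L·min⁻¹."""
    return IndividualProfile(age=25, mass=75, height=175, sex="male", vo2max=4.0)


@pytest.fixture(scope="session")
def unfit_profile() -> IndividualProfile:
    return IndividualProfile(age=25, mass=75, height=175, sex="male", vo2max=2.5)


@pytest.fixture(scope="session")
def fit_basic(fit_profile):
    return derive_basic_cardio(fit_profile)


@pytest.fixture(scope="session")
def unfit_basic(unfit_profile):
    return derive_basic_cardio(unfit_profile)
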