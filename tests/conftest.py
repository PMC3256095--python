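import pytest
from hypothesis import settings

from t2dprev import default_bundle, fixture_scenario

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from t2dprev.mortality import MortalityModel


@pytest.fixture()
def bundle():
    return default_bundle()


@pytest.fixture()
def zero_mortality():
    return MortalityModel.zero()


@pytest.fixture(scope="session")
def paper_base():
    """The base-case parameter set with the synthetic German-like life table."""
    return fixture_scenario("paper-base")
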