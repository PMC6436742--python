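import pytest
from hypothesis import settings

from apisim import EconomicParams, ForageParams, YieldRamp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def econ():
    return EconomicParams()


@pytest.fixture(scope="session")
def forage_params():
    return ForageParams()


@pytest.fixture(scope="session")
def ramp():
    return YieldRamp()
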