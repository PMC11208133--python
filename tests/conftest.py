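import pytest
from hypothesis import HealthCheck, settings

from kmerwalk import Alphabet, DesignParams, design_library

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dna():
    return Alphabet.dna()


@pytest.fixture(scope="session")
def act():
    return Alphabet.three_letter()


@pytest.fixture(scope="session")
def small_design(dna):
    """The 10-sequence m=4, k=3, L=8 design."""
    return design_library(DesignParams(dna, 3, 8))


@pytest.fixture(scope="session")
def medium_design(dna):
    """The 36-sequence m=4, k=4, L=10 design used by the pattern bounds."""
    return design_library(DesignParams(dna, 4, 10))
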