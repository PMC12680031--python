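import pytest

from proguide.cts_library import CtsCandidate, first_passing_candidate
from proguide.proguide_design import build_cassette, build_proguide

SPACER = "GACGTCTAAGAAACCATTAT"


@pytest.fixture(scope="session")
def cts():
    """A composition-filter-passing CTS used across construct tests."""
    return first_passing_candidate(seed=3)


@pytest.fixture(scope="session")
def example_cts():
    """The worked-example CTS with an alternating protospacer."""
    return CtsCandidate("ACGTACGTACGTACGTACGT", "TGG", "example")


@pytest.fixture(scope="session")
def ir1_construct(cts):
    return build_proguide(SPACER, cts, "IR1", name="ir1")


@pytest.fixture(scope="session")
def dr1_construct(cts):
    return build_proguide(SPACER, cts, "DR1", name="dr1")


@pytest.fixture()
def dual_cassette():
    return build_cassette("dual_polyT", 8, 8)
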