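import pytest

from bsim.rosters import load_roster
from bsim.simulate import STUDY1_PARAMS, STUDY2_PARAMS, simulate_cohort


@pytest.fixture(scope="session")
def roster1():
    return load_roster("study1")


@pytest.fixture(scope="session")
def roster2():
    return load_roster("study2")


@pytest.fixture(scope="session")
def cohort1(roster1):
    """Small equal-validity cohort at the published generative parameters."""
    return simulate_cohort(20, STUDY1_PARAMS, roster1, seed=20260919)


@pytest.fixture(scope="session")
def cohort2(roster2):
    """Small varying-accuracy cohort at the published generative parameters."""
    return simulate_cohort(20, STUDY2_PARAMS, roster2, seed=20260920)
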