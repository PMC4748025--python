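import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from proxsoc.records import AgeClass, Individual, Sex
from proxsoc.simulate import SocietyConfig, simulate_study


@pytest.fixture
def tiny_roster():
    return [
        Individual("F01", Sex.FEMALE, AgeClass.ADULT),
        Individual("F02", Sex.FEMALE, AgeClass.ADULT),
        Individual("M01", Sex.MALE, AgeClass.ADULT),
        Individual("M02", Sex.MALE, AgeClass.ADULT),
        Individual("M03", Sex.MALE, AgeClass.SUBADULT),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One full default-parameter study, shared across the session."""
    config = SocietyConfig(seed=1)
    truth, states, focals, adlib = simulate_study(config)
    return config, truth, states, focals, adlib


@pytest.fixture(scope="session")
def small_sim():
    """A short, small study for fast end-to-end tests."""
    config = SocietyConfig(
        seed=11, n_parties=2, units_per_party=(2, 2), n_bachelors=2,
        study_days=98,
    )
    truth, states, focals, adlib = simulate_study(config)
    return config, truth, states, focals, adlib
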