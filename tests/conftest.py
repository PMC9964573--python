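"""Shared fixtures: one simulated session reused across the suite."""

import numpy as np
import pytest

from vo2lstm import synthetic


@pytest.fixture(scope="session")
def protocol():
    return synthetic.generate_protocol()


@pytest.fixture(scope="session")
def subject():
    return synthetic.SubjectProfile()


@pytest.fixture(scope="session")
def motion_and_steps(protocol, subject):
    """Default-protocol motion trace plus ground-truth step boundaries."""
    return synthetic.simulate_steps(protocol, subject, seed=101)


@pytest.fixture(scope="session")
def physio(protocol, subject):
    return synthetic.simulate_physiology(protocol, subject, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
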