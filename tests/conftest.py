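"""Shared fixtures: one synthetic world generated once per session."""

import numpy as np
import pytest

from hydrofowl.synthetic import (
    default_effort,
    default_niches,
    generate_landscape,
    simulate_banding_records,
)


@pytest.fixture(scope="session")
def stack():
    return generate_landscape(11)


@pytest.fixture(scope="session")
def niches():
    return default_niches()


@pytest.fixture(scope="session")
def effort(stack):
    return default_effort(stack, 12)


@pytest.fixture(scope="session")
def records(stack, niches, effort):
    return simulate_banding_records(niches, effort, stack, 13)


@pytest.fixture(scope="session")
def true_windows(niches):
    return {n.species: n.true_windows() for n in niches}
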