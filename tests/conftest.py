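import numpy as np
import pytest

from dmtasim.fixtures import default_fixture, default_reactions


@pytest.fixture(scope="session")
def fixture0():
    """The standard desk-scale testbed (seed 0), shared across the session."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def templates():
    return default_reactions()


@pytest.fixture(scope="session")
def template_map(templates):
    return {t.template_id: t for t in templates}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
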