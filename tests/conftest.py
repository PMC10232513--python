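import pytest
from hypothesis import settings

import critloads as cl

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return cl.default_parameters()


@pytest.fixture(scope="session")
def fixtures():
    return cl.worked_fixtures()


@pytest.fixture(scope="session")
def small_grid():
    """A 30x30 seeded synthetic stack plus its parameter set."""
    cfg = cl.SynthConfig(nrows=30, ncols=30, seed=7)
    return cl.generate_grid(cfg)
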