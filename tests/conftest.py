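import pytest
from hypothesis import settings

from mostsim.fingerprints import FingerprintCache

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mostsim.simulate import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def cache():
    """Session-wide Morgan fingerprint cache (structures repeat across tests)."""
    return FingerprintCache("morgan")


@pytest.fixture(scope="session")
def small_sim(cache):
    """A 10-target panel with the planted structure-activity law."""
    return generate_panel(GeneratorConfig(seed=20170311, n_targets=10), cache=cache)


@pytest.fixture(scope="session")
def small_panel(small_sim):
    return small_sim.panel
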