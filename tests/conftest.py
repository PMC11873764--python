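import numpy as np
import pytest
from hypothesis import settings

from neofc import SimulationConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_config():
    """Small but structurally complete cohort config for fast tests."""
    return SimulationConfig(n_music=3, n_control=3, n_volumes=120, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A generated 3+3-subject cohort on disk, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = SimulationConfig(n_music=3, n_control=3, n_volumes=120, seed=7)
    manifest = simulate_cohort(config, out)
    return out, config, manifest
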