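import pytest

from srnase_evol import aa_distance_matrix, build_selection_profile
from srnase_evol.synth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Reference simulated dataset at the default study conditions."""
    config = SimulationConfig(seed=1)
    alignment, truth = simulate_dataset(config)
    return config, alignment, truth


@pytest.fixture(scope="session")
def default_profile(default_sim):
    _config, alignment, _truth = default_sim
    return build_selection_profile(alignment)


@pytest.fixture(scope="session")
def default_matrix(default_sim):
    _config, alignment, _truth = default_sim
    return aa_distance_matrix(alignment)
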