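import pytest

from syntriad.pipeline import run_on_simulation
from syntriad.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """Simulation under the default study conditions (fixed seed)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline output on the default simulation."""
    return run_on_simulation(default_sim)


@pytest.fixture(scope="session")
def small_sim():
    """A lighter simulation for structural checks."""
    return simulate(SimulationConfig(seed=7, genes_per_chromosome=80))
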