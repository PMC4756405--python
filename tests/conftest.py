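import pytest

from heteroseq import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One desk-scale synthetic study shared across tests."""
    return simulate_all(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A tiny study for fast IO/pipeline round trips."""
    return simulate_all(
        SimConfig(seed=7, n_genes=300, mean_library_size=60_000)
    )
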