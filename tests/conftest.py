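import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset shared across read-only tests."""
    from xsilence import SimulationSpec, simulate_dataset

    spec = SimulationSpec(seed=7, genome_length=150_000, n_islands=25)
    genome, truth, coverage, tss = simulate_dataset(spec)
    return spec, genome, truth, coverage, tss
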