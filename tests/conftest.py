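import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trapsim import SimulationParameters, default_architecture, run_replicates

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_arch():
    return default_architecture()


@pytest.fixture(scope="session")
def neutral_default_trajs(default_arch):
    """30 established neutral default invasions (u=0.1, N=1000, 500
    generations) shared by the invasion-dynamics acceptance checks."""
    params = SimulationParameters(
        u=0.1, N=1000, n_seed=10, generations=500, seed=11, replicates=30
    )
    return run_replicates(default_arch, params, established_only=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
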