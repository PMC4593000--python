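import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150915)


@pytest.fixture(scope="session")
def small_screen_pair():
    """A small but complete synthetic screen pair with planted interactions."""
    from qfa.synthetic_data import SimulationConfig, generate_screen_pair

    cfg = SimulationConfig(
        n_genes=60, n_replicates=4, planted_fraction=0.1,
        planted_effect_range=(0.5, 0.5), noise_sigma=0.05, seed=42,
    )
    control, query, truth = generate_screen_pair(cfg)
    return cfg, control, query, truth
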