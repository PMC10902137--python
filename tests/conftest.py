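import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import germscan as gs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    return gs.SimulationConfig(
        n_genotypes=40, n_snps=150, n_causal=2, causal_effect_sizes=0.8, rng_seed=17
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return gs.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_trialset(small_config, small_panel):
    gm, registry = small_panel
    return gs.simulate_trials(small_config, gm, registry)


@pytest.fixture(scope="session")
def small_relative(small_trialset):
    traits = gs.trait_table(small_trialset.trials)
    return gs.relative_indices(traits)
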