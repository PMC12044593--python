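import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import acfsa

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 1


@pytest.fixture(scope="session")
def paper_spec():
    return acfsa.paper_like_spec(SEED)


@pytest.fixture(scope="session")
def paper_table(paper_spec):
    return acfsa.generate_response_table(paper_spec)


@pytest.fixture(scope="session")
def fast_config():
    """Run configuration with a reduced Monte-Carlo budget for the error
    estimate; the ARI/elimination path is identical to the default."""
    return acfsa.ACFSAConfig(kmeans_seed=SEED, mc_seed=SEED, n_mc=20_000)


@pytest.fixture(scope="session")
def paper_trace(paper_table, fast_config):
    """Full chi-squared elimination 30 → 2 on the default screen."""
    return acfsa.run_acfsa(paper_table,
                           acfsa.StoppingCondition(min_sensors=2),
                           fast_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
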