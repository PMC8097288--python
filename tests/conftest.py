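import dendropy
import pytest
from hypothesis import HealthCheck, settings

from rniikit import SimulationConfig, simulate_family

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def small_sim():
    """A modest default-rate simulated family shared across tests."""
    return simulate_family(SimulationConfig(n_tips=30, seed=11))


@pytest.fixture(scope="session")
def frozen_sim():
    """A zero-rate simulation: every tip equals the root blueprint."""
    cfg = SimulationConfig(
        n_tips=20, seed=5, rate_nterm=0.0, rate_csd=0.0, rate_rnii=0.0,
        rate_linker=0.0, loss_rate=0.0,
    )
    return simulate_family(cfg)
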