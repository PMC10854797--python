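import numpy as np
import pytest

from larynxsim.cohort import generate_reference_cohort
from larynxsim.engine import EngineContext, SimulationConfig, generate_population
from larynxsim.larynx import larynx_actions, load_shipped_module
from larynxsim.registry import default_bundle


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def module():
    return load_shipped_module()


@pytest.fixture()
def ctx(bundle):
    return EngineContext(bundle=bundle, actions=larynx_actions())


@pytest.fixture(scope="session")
def small_population(bundle, module):
    """A small prevalence-mode population shared across read-only tests."""
    ctx = EngineContext(bundle=bundle, actions=larynx_actions())
    config = SimulationConfig(mode="prevalence", target_alive=4000, seed=42)
    return generate_population(config, [module], ctx)


@pytest.fixture(scope="session")
def enriched_pool(bundle, module):
    """A small enriched-mode case repository shared across cohort tests."""
    ctx = EngineContext(bundle=bundle, actions=larynx_actions())
    config = SimulationConfig(mode="enriched", target_alive=6000, seed=7)
    return generate_population(config, [module], ctx)


@pytest.fixture(scope="session")
def reference_cohort(bundle):
    return generate_reference_cohort(20000, bundle, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
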