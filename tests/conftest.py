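import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_spec():
    from elderdep.fixtures import FixtureSpec

    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def panel(fixture_spec):
    from elderdep.fixtures import gen_expert_panel

    return gen_expert_panel(fixture_spec)


@pytest.fixture(scope="session")
def table_set(panel):
    from elderdep.agents import TableSet
    from elderdep.tables import average_tables

    nondep, dep, imp = average_tables(panel, "TypeAll")
    return TableSet(nondep, dep, imp)


@pytest.fixture(scope="session")
def schedule(fixture_spec):
    from elderdep.fixtures import gen_mortality
    from elderdep.population import compute_mortality_schedule

    return compute_mortality_schedule(gen_mortality(fixture_spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
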