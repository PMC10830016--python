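import pytest
from hypothesis import HealthCheck, settings

import triweb as tw

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def net_ma_small() -> tw.TripartiteNetwork:
    return tw.fixture("F_MA_small")


@pytest.fixture
def net_sym() -> tw.TripartiteNetwork:
    return tw.fixture("F_sym")


@pytest.fixture
def net_aa_chain() -> tw.TripartiteNetwork:
    return tw.fixture("F_AA_chain")


@pytest.fixture
def net_keystone() -> tw.TripartiteNetwork:
    return tw.fixture("F_keystone")


@pytest.fixture
def fan_net() -> tw.TripartiteNetwork:
    """A mid-sized random fan network, fixed seed."""
    return tw.generate(tw.GeneratorConfig(sizes=(30, 30, 30), seed=11))


@pytest.fixture
def chain_net() -> tw.TripartiteNetwork:
    """A mid-sized random chain network, fixed seed."""
    return tw.generate(
        tw.GeneratorConfig(
            sizes=(30, 30, 30), topology="chain", signs=("-", "-"), seed=12
        )
    )
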