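import pytest

from mcoascan.simulate import PanelConfig, simulate_panel


@pytest.fixture(scope="session")
def default_sim():
    """One default panel simulation shared across read-only tests."""
    return simulate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return PanelConfig(seed=1)
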