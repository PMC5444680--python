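import pytest

from hybridsnv import SimulationConfig, kras


@pytest.fixture(scope="session")
def probeset():
    """The default KRAS probeset (1 PM + 45 1MM + 495 2MM probes)."""
    return kras.default_probeset()


@pytest.fixture(scope="session")
def panel():
    """The 12 panel hypotheses (three substitutions at each hotspot position)."""
    return kras.kras_panel()


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()
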