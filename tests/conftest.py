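import pytest
from hypothesis import settings

from paleoprev import load_timescale, scenario_bundle

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ts():
    return load_timescale()


@pytest.fixture(scope="session")
def tiny_amp_bundle():
    return scenario_bundle("amplification", preset="tiny", seed=42)


@pytest.fixture(scope="session")
def tiny_neutral_bundle():
    return scenario_bundle("neutral", preset="tiny", seed=42)


@pytest.fixture(scope="session")
def paper_amp_bundle():
    return scenario_bundle("amplification", preset="paper", seed=7)
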