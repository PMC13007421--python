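import pytest
from hypothesis import settings

from gmoscreen.panel import builtin_panel
from gmoscreen.decoder import builtin_matrix
from gmoscreen.construct_factory import ConstructSpec, build_standard_plasmid

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def soy_panel():
    return builtin_panel("soybean")


@pytest.fixture(scope="session")
def maize_panel():
    return builtin_panel("maize")


@pytest.fixture(scope="session")
def soy_matrix():
    return builtin_matrix("soybean")


@pytest.fixture(scope="session")
def maize_matrix():
    return builtin_matrix("maize")


@pytest.fixture(scope="session")
def soy_plasmid(soy_panel):
    return build_standard_plasmid(ConstructSpec(crop="soybean", seed=11), soy_panel)


@pytest.fixture(scope="session")
def maize_plasmid(maize_panel):
    return build_standard_plasmid(ConstructSpec(crop="maize", seed=13), maize_panel)
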