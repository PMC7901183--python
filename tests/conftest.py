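import pytest

from cfmix import PanelSpec, generate_panel, simulate_pedigree


@pytest.fixture(scope="session")
def default_panel():
    """The full 739-region study panel."""
    return generate_panel(seed=11)


@pytest.fixture(scope="session")
def small_panel():
    """A quick 60-SNP panel for unit-scale simulations."""
    spec = PanelSpec(autosome_counts={"21": 60}, n_zfx=5, n_zfy=5)
    return generate_panel(spec, seed=7)


@pytest.fixture(scope="session")
def pedigree(default_panel):
    return simulate_pedigree(default_panel, seed=23)
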