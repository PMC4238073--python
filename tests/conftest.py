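import pytest

from megakey import GeneratorConfig, build_matrix, generate_species
from megakey.datasets import shadeae_description, shadeae_text


@pytest.fixture(scope="session")
def shadeae():
    """The packaged worked-example description (M. shadeae), parsed strictly."""
    return shadeae_description()


@pytest.fixture(scope="session")
def shadeae_tsv():
    return shadeae_text()


@pytest.fixture(scope="session")
def fauna50():
    """The reference synthetic fauna: 50 species, seed 42, coded separation >= 3."""
    return generate_species(GeneratorConfig(n_species=50, seed=42,
                                            min_pairwise_separation=3))


@pytest.fixture(scope="session")
def matrix50(fauna50):
    return build_matrix(fauna50)
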