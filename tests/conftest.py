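import pytest

from delmol.fixtures import FixtureSpec, generate_fixtures

NAFCILLIN = "CCOc1ccc2ccccc2c1C(=O)NC1C(=O)N2C1SC(C)(C)C2C(=O)O"


@pytest.fixture(scope="session")
def library200():
    """Seeded 200-molecule synthetic drug-like library."""
    return generate_fixtures(FixtureSpec(n_molecules=200, seed=1))


@pytest.fixture(scope="session")
def library20(library200):
    return library200[:20]


@pytest.fixture(scope="session")
def trained_jtvae(library200):
    """Tiny junction-tree model pretrained on the fixture library."""
    from delmol.generative import ModelConfig, SequenceVAE

    model = SequenceVAE.from_dataset(library200, ModelConfig.tiny(),
                                     kind="jtvae", seed=0)
    model.fit(library200, epochs=12)
    return model


@pytest.fixture(scope="session")
def trained_fragvae(library200):
    from delmol.generative import ModelConfig, SequenceVAE

    model = SequenceVAE.from_dataset(library200, ModelConfig.tiny(),
                                     kind="fragvae", seed=0)
    model.fit(library200, epochs=12)
    return model
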