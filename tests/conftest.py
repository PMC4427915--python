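import pytest

from phosmap.architecture import load_registry
from phosmap.fixtures import generate_synthetic, paper_fixture


@pytest.fixture(scope="session")
def bundle():
    """Curated literature fixture bundle (peptides, stubs, sites, features)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def registry():
    """Packaged collagen/MMP/BMP domain-architecture registry."""
    return load_registry()


@pytest.fixture(scope="session")
def synthetic():
    """One deterministic synthetic multi-source bundle."""
    return generate_synthetic(seed=7)


@pytest.fixture()
def synthetic_dir(tmp_path, synthetic):
    """The synthetic bundle written out as FASTA + TSVs + truth JSON."""
    return synthetic.write(tmp_path / "bundle")
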