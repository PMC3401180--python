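import pytest

from nestkin import genotype_io


@pytest.fixture(scope="session")
def reference_queens():
    """Packaged queen genotypes (curated view): (loci, {colony: genotypes})."""
    return genotype_io.load_fixture_queens()


@pytest.fixture(scope="session")
def reference_coords():
    return genotype_io.load_fixture_coords()
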