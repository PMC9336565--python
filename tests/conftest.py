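import pytest

from pseudoscan import fixtures
from pseudoscan.genome_io import feature_nt


@pytest.fixture(scope="session")
def small_fx():
    """24 genes / 12 families: fast enough for per-test pipelines."""
    return fixtures.small_fixture(seed=5)


@pytest.fixture(scope="session")
def small_reference(small_fx):
    return {
        f.locus_tag: feature_nt(small_fx.genome, f)
        for f in small_fx.genome.cds_features()
    }


@pytest.fixture(scope="session")
def fx200():
    """The standard 200-gene / 60-family benchmarking fixture."""
    return fixtures.fixture_200(seed=11)


@pytest.fixture(scope="session")
def fx200_reference(fx200):
    return {
        f.locus_tag: feature_nt(fx200.genome, f)
        for f in fx200.genome.cds_features()
    }
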