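import numpy as np
import pytest

from dmrkit import FixtureSpec, generate_fixtures
from dmrkit.genome_regions import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def sizes():
    return {"chr1": 1_000_000, "chr2": 30_000}


@pytest.fixture
def plus_gene():
    return GeneModel("GENE1", "TX1", "chr1", "+", 10_000, 50_000)


@pytest.fixture
def minus_gene():
    return GeneModel("GENE2", "TX2", "chr1", "-", 10_000, 50_000)


@pytest.fixture(scope="session")
def small_wgbs_fixture(tmp_path_factory):
    """A 80-gene WGBS fixture with planted DMRs and missing sites."""
    out = tmp_path_factory.mktemp("fx_small")
    spec = FixtureSpec(n_genes=80, frac_planted=0.25, missing_rate=0.1, dialect="wgbs")
    paths = generate_fixtures(11, spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def small_hmst_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("fx_hmst")
    spec = FixtureSpec(n_genes=60, frac_planted=0.25, dialect="hmst")
    paths = generate_fixtures(12, spec, out)
    return spec, paths
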