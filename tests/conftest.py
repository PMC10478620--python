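import pytest

from gars.assoc import assoc_linear, rank_snps
from gars.simulate import fixture_small
from gars.trace import GarsConfig, gars_trace


@pytest.fixture(scope="session")
def small_data():
    """Fixed-seed 300 x 3,000 cohort (30 QTLs, h2 = 0.3) shared across the suite."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_assoc(small_data):
    geno, pheno, _ = small_data
    return assoc_linear(geno, pheno, "trait")


@pytest.fixture(scope="session")
def small_ranked(small_assoc):
    return rank_snps(small_assoc)


@pytest.fixture(scope="session")
def small_trace(small_data, small_assoc, small_ranked):
    geno, pheno, _ = small_data
    n_testable = int(small_assoc["testable"].sum())
    return gars_trace(
        geno, pheno, "trait", small_ranked[:n_testable], GarsConfig(step=500)
    )
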