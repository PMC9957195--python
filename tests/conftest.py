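import pytest

from satzone import datasets


@pytest.fixture(scope="session")
def cpp_bands():
    return datasets.load_band_table("CPP")


@pytest.fixture(scope="session")
def cpe_bands():
    return datasets.load_band_table("CPE")


@pytest.fixture(scope="session")
def genotypes():
    return datasets.load_genotype_tables()


@pytest.fixture(scope="session")
def transect_sites():
    return datasets.load_transect_sites()
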