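import pytest

import prfcub as pc


@pytest.fixture(scope="session")
def default_dataset() -> pc.SyntheticDataset:
    """The default synthetic genome (2000 genes, seed 1), shared across tests."""
    return pc.generate(pc.default_config(seed=1))


@pytest.fixture(scope="session")
def default_sites(default_dataset):
    return pc.scan_and_frameshift(default_dataset.genes)


@pytest.fixture(scope="session")
def default_table(default_dataset):
    return pc.reference_table(default_dataset)


@pytest.fixture(scope="session")
def small_dataset() -> pc.SyntheticDataset:
    """A small genome for cheap end-to-end checks."""
    return pc.generate(pc.default_config(seed=7, n_genes=120))
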