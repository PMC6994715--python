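import numpy as np
import pytest

from fusil.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A modest simulated dataset shared by read-only tests."""
    config = SyntheticConfig(n_genes=800, n_cell_lines=30, seed=11)
    return generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
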