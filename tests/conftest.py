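import numpy as np
import pytest

from codonstab.codon_core import frequency_matrix_from_counts
from codonstab.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def coupled_dataset():
    """A small synthetic genome with a clear optimality-stability coupling."""
    return simulate_dataset(
        SimulationConfig(seed=11, n_genes=200, gene_length_range=(100, 300))
    )


@pytest.fixture(scope="session")
def coupled_frequencies(coupled_dataset):
    return frequency_matrix_from_counts(coupled_dataset.counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
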