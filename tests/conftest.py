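import numpy as np
import pandas as pd
import pytest

import hicdelta as hd
from hicdelta.genome import make_bin_table


@pytest.fixture(scope="session")
def small_config():
    """Two small chromosomes, modest library: fast but structurally complete."""
    return hd.SimulationConfig(
        n_chromosomes=2,
        chrom_length=8_000_000,
        resolution=400_000,
        library_size=100_000,
        n_switched_bins=6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    maps, truth = hd.simulate_contact_maps(small_config)
    return maps, truth


@pytest.fixture(scope="session")
def small_expression(small_config, small_sim):
    _, truth = small_sim
    return hd.simulate_expression(small_config, truth)


@pytest.fixture()
def bins12():
    return make_bin_table({"chr1": 12 * 400_000}, 400_000)


def contact_from_dense(matrix, resolution=400_000, chrom="chr1"):
    matrix = np.asarray(matrix, dtype=float)
    bins = make_bin_table({chrom: matrix.shape[0] * resolution}, resolution)
    return hd.ContactMatrix(bins=bins, matrix=matrix, resolution=resolution)


@pytest.fixture()
def dense_factory():
    return contact_from_dense
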