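import numpy as np
import pytest

import platesum as ps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_dataset():
    """A deterministic spiked dataset small enough for exhaustive checks."""
    cfg = ps.scenario(
        "default", n_genes=300, cells_per_plate_range=(15, 25), de_fraction=0.1, seed=99
    )
    return ps.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def summed_fixture(small_dataset):
    """Filtered counts, per-plate sums and matched truth labels."""
    counts, kept = ps.filter_low_abundance(small_dataset.counts)
    summed = ps.sum_by_plate(counts, small_dataset.design)
    return counts, summed, small_dataset.true_de[kept], small_dataset.design
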