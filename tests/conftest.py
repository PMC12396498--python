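import numpy as np
import pytest

from lactolink.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact dataset with one planted co-expressed pair and one
    gene-HMO link, shared by read-only tests."""
    cfg = SimConfig(
        seed=20240917,
        n_donors=6,
        samples_per_donor=3,
        n_genes=40,
        cells_per_sample_range=(200, 300),
        planted_pairs=[("G0001", "G0002", "LC2", 8.0)],
        gene_hmo_links=[("G0003", "2'FL", 1.0, "LC2")],
        mean_overrides=[("G0001", "LC2", 0.3), ("G0002", "LC2", 0.3)],
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=20240917,
        n_donors=6,
        samples_per_donor=3,
        n_genes=40,
        cells_per_sample_range=(200, 300),
        planted_pairs=[("G0001", "G0002", "LC2", 8.0)],
        gene_hmo_links=[("G0003", "2'FL", 1.0, "LC2")],
        mean_overrides=[("G0001", "LC2", 0.3), ("G0002", "LC2", 0.3)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
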