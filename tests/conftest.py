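import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("tadlink").setLevel(logging.ERROR)

SMALL_SCALE = dict(
    chrom_sizes={"chr1": 4_000_000, "chr2": 4_000_000},
    n_tads_per_celltype=12,
    tad_length_range=(120_000, 400_000),
    n_genes=40,
    n_dmrs=30,
    n_spatial_link_pairs=2,
)


def small_config(**overrides):
    from tadlink.simulate import SimulationConfig

    kwargs = dict(SMALL_SCALE)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    from tadlink.simulate import generate_dataset

    return generate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale synthetic dataset (2 x 20 Mb, 60 TADs, 150 DMRs)."""
    from tadlink.simulate import generate_dataset, SimulationConfig

    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def uniform_genome():
    """A composition-homogeneous 2 x 1 Mb genome for sampler tests."""
    from tadlink.simulate import SimulationConfig, generate_genome

    cfg = SimulationConfig(chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000}, seed=5)
    return generate_genome(cfg, np.random.default_rng(5))
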