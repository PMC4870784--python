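import numpy as np
import pytest

from xitools import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    return sim.SimConfig(seed=11, chrom_length_bp=2_000_000,
                         n_chrom_autosome=1, n_genes_x=40, n_genes_autosome=40)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    rng = np.random.default_rng(small_config.seed)
    return sim.simulate_annotation(small_config, rng)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
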