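import numpy as np
import pytest

from diphic.simulate import SimConfig, make_truth


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(chrom_lengths={"chr1": 4_000_000, "chr2": 2_000_000},
                     n_contacts=100_000, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return make_truth(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def symmetric_gamma(rng, n, shape=2.0, scale=5.0):
    """Dense symmetric strictly-positive test matrix."""
    m = rng.gamma(shape, scale, (n, n))
    m = np.triu(m)
    return m + np.triu(m, 1).T
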