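import numpy as np
import pytest
from hypothesis import settings

from scda_impute.genotype_io import GenotypeMatrix
from scda_impute.simulate import CrossSimConfig, PopSimConfig, simulate_cross, simulate_population

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cross():
    """Fully observed 2-class cross matrix with long parental runs."""
    return simulate_cross(CrossSimConfig(n_samples=60, n_markers=48, switch_rate=0.05, seed=7))


@pytest.fixture
def small_pop():
    """Fully observed 3-class diploid matrix with block LD."""
    return simulate_population(
        PopSimConfig(n_samples=60, n_markers=48, block_length=8, seed=11)
    )


@pytest.fixture
def toy_diploid():
    """Hand-sized 6x5 diploid matrix with a few missing entries."""
    values = np.array(
        [
            [1, 2, 3, 1, 2],
            [1, 0, 3, 1, 2],
            [2, 2, 0, 1, 3],
            [1, 2, 3, 0, 2],
            [3, 1, 2, 1, 0],
            [1, 2, 3, 1, 2],
        ]
    )
    return GenotypeMatrix(values, 3)


def random_corrupted_matrix(seed: int, n: int = 8, m: int = 6, n_classes: int = 3):
    """Random valid genotype matrix with ~20% missing entries."""
    r = np.random.default_rng(seed)
    values = r.integers(1, n_classes + 1, size=(n, m))
    miss = r.random((n, m)) < 0.2
    values[miss] = 0
    # ensure every column keeps at least one observed entry
    for j in range(m):
        if (values[:, j] == 0).all():
            values[r.integers(0, n), j] = 1
    return GenotypeMatrix(values, n_classes)
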