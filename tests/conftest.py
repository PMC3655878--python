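import numpy as np
import pytest

from multiphen import GenotypeVector, PhenotypeMatrix, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_config():
    """The reference simulation design: n=300, m=10, delta=1.2, r=0.5."""
    return SimulationConfig(
        allele_freq=0.3,
        n_samples=300,
        n_phenotypes=10,
        effect_size=1.2,
        correlation=0.5,
        seed=20240917,
    )


@pytest.fixture
def small_dataset(rng):
    """n=60, m=3 dataset with a moderate genotype effect on every trait."""
    g = GenotypeVector(rng.integers(0, 3, 60))
    values = rng.standard_normal((60, 3)) + 0.4 * g.counts[:, None]
    return PhenotypeMatrix(values), g
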