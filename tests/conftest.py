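import numpy as np
import pytest

from strland import SpectrumParams, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """60 samples at 20 loci with a range of variabilities."""
    specs = [
        (f"L{i:03d}", SpectrumParams(major_allele_bp=2 * (10 + i), period=2, decay=0.1 + 0.03 * i))
        for i in range(20)
    ]
    return simulate_population(specs, n_samples=60, seed=7)
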