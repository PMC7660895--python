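import numpy as np
import pytest

import starfunc as sf


@pytest.fixture(scope="session")
def locus():
    """Small synthetic locus shared by read-only tests."""
    return sf.generate_synthetic_locus(
        n_alleles_per_class=(3, 3, 3), window_length=600, n_af_sites=15,
        seed=7)


@pytest.fixture(scope="session")
def curated(locus):
    return [d for d in locus.definitions if d.function.is_curated]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
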