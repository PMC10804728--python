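import numpy as np
import pytest

from dosiofuse.phantom import make_phantom_pair, simulate_cohort


@pytest.fixture(scope="session")
def phantom_pair():
    """Co-registered CT/dose/GTV phantom, speckle-textured tumor."""
    return make_phantom_pair((24, 24, 24), tumor_radius_mm=8.0,
                             texture_mode="speckle", seed=42)


@pytest.fixture(scope="session")
def planted_cohort():
    """5-center cohort, 3 informative of 20 features, 30% censoring."""
    beta = np.zeros(20)
    beta[:3] = [1.2, -1.0, 0.8]
    return simulate_cohort([80] * 5, beta, baseline=(1.2, 1000.0),
                           censor_rate=0.3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
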