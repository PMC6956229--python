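import io

import numpy as np
import pytest

from rollcompact import metrology, synthetic


@pytest.fixture(scope="session")
def noiseless_library():
    """Default 81-material library at zero noise (seed 0)."""
    cfg = synthetic.SyntheticConfig(seed=0, sigma_ts=0.0, sigma_sf=0.0)
    return synthetic.generate_library(cfg)


@pytest.fixture(scope="session")
def noisy_library():
    """Default 81-material library at the default noise levels."""
    return synthetic.generate_library(synthetic.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_profiles(noiseless_library):
    _, ribbons, _ = noiseless_library
    samples = metrology.read_ribbon_table(io.StringIO(ribbons.to_csv(index=False)))
    return metrology.profiles_from_table(samples), samples


@pytest.fixture
def simple_psd():
    from rollcompact.descriptors import PSDHistogram

    return PSDHistogram(
        bin_edges=np.array([0.0, 25.0, 50.0, 100.0, 200.0]),
        frequency=np.array([10.0, 20.0, 40.0, 30.0]),
        d10=25.0, d50=75.0, d90=160.0,
    )
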