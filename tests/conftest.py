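import numpy as np
import pytest

from dscquant import bolus_detection as bd
from dscquant import concentration as cc
from dscquant.synthetic_phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noisy leaky phantom at the default study conditions (seed 0)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free, leakage-free phantom for exactness checks."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, tumor_k2=0.0))


@pytest.fixture(scope="session")
def noiseless_conc(noiseless_phantom):
    """Detected timing + concentration series of the noiseless phantom."""
    series, _ = noiseless_phantom
    trimmed, timing = bd.detect_bolus(series)
    conc = cc.to_concentration(trimmed, cc.baseline_map(trimmed, timing), timing)
    return trimmed, timing, conc


@pytest.fixture(scope="session")
def noisy_conc(default_phantom):
    series, _ = default_phantom
    trimmed, timing = bd.detect_bolus(series)
    conc = cc.to_concentration(trimmed, cc.baseline_map(trimmed, timing), timing)
    return trimmed, timing, conc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
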