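import numpy as np
import pytest

from stromascope.phasor import build_calibration
from stromascope.simulate import DecaySimSpec, simulate_decay


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ideal_calibration():
    """Calibration built from an ideally simulated 3.6 ns standard
    (50 ns period, 256 bins, harmonics 1-8)."""
    ref = simulate_decay(
        DecaySimSpec([3.6], [1.0], total_photons=1e6, noise="none")
    )
    return build_calibration(ref, tau_ref_ns=3.6)
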