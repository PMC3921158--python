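import numpy as np
import pytest

from plinet.montage import Montage
from plinet.simulate import BandComponent, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_montage():
    return Montage(("Fz", "Cz", "Pz", "Oz"), 500.0)


@pytest.fixture
def beta_pair_config():
    """Two-channel beta-only oscillator config for fast pairwise checks.

    The beta band is wide enough that uncoupled oscillators decorrelate
    well within one 4096-sample epoch, which makes the near-zero PLI
    statements of the coupling contract testable at this epoch length.
    """
    return SimulationConfig(
        n_channels=2,
        channel_labels=("Fz", "Pz"),
        duration=9.0,
        band_components=(BandComponent("beta", 20.0, phase_sigma=0.22,
                                       freq_spread=4.0),),
        noise_amplitude=0.0,
    )
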