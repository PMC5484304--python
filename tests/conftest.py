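import numpy as np
import pytest

import seqshim as ss


@pytest.fixture(scope="session")
def phantom():
    return ss.generate_phantom()


@pytest.fixture(scope="session")
def qset(phantom):
    return ss.build_q_matrices(phantom)


@pytest.fixture(scope="session")
def vops(qset):
    return ss.compress_vops(qset, 0.03)


@pytest.fixture(scope="session")
def sens(phantom):
    """Emulated measured sensitivities at the 45° target."""
    return ss.emulate_b1_measurement(phantom, noise_sd=0.02, seed=7).with_target(
        np.deg2rad(45.0)
    )


@pytest.fixture(scope="session")
def limits():
    return ss.HardwareLimits()


@pytest.fixture(scope="session")
def gauss_pulse():
    return ss.RFPulse(tau=1.7, preset="measured-gaussian")


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Circular, uniform-tissue phantom with a perfectly symmetric 4-channel
    coil (no element jitter): the rotational-symmetry reference case."""
    spec = ss.PhantomSpec(
        n_channels=4,
        semi_axes=(80.0, 80.0),
        blob_conductivity=0.5,
        roi_center=(0.0, 0.0),
        gain_jitter=0.0,
        phase_jitter_deg=0.0,
    )
    return ss.generate_phantom(spec)
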