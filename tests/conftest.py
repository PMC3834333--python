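import numpy as np
import pytest

from striacal import preprocess, synth


@pytest.fixture(scope="session")
def single_pulse_protocol():
    return preprocess.StimulusProtocol([1.5], post_window=4.0)


@pytest.fixture(scope="session")
def train_protocol():
    return preprocess.StimulusProtocol.train()


@pytest.fixture(scope="session")
def noiseless():
    return synth.NoiseParams(read_noise_sd=0.0, shot_noise=False)


@pytest.fixture(scope="session")
def geometry():
    return synth.make_geometry(seed=1)


@pytest.fixture(scope="session")
def noiseless_single_pulse_stack(geometry, single_pulse_protocol, noiseless):
    """Noise-free movie with spatial gradients, plus its ground-truth maps."""
    kin = synth.KineticsParams(amplitude_a=0.3, tau=0.7)
    stack = synth.simulate_stack(
        geometry, kin, single_pulse_protocol, noiseless, duration=4.0
    )
    f0_map, amp_map = synth.build_model_maps(geometry, kin)
    return stack, kin, f0_map, amp_map


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def dff_from_stack(stack, protocol):
    sub = preprocess.subtract_dark(stack)
    return preprocess.compute_dff(sub, preprocess.compute_f0(sub, protocol))
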