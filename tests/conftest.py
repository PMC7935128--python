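import numpy as np
import pytest

from mousegait.synthetic_data import generate_trial, make_preset


@pytest.fixture(scope="session")
def control_trial_truth():
    """Noise-free control trial at the default resolution, with truth."""
    cfg = make_preset("control", 14)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def coarse_trial_truth():
    """Noise-free control trial at 25 frames/cycle, 100 fps (6 cycles)."""
    cfg = make_preset("control", 14, frames_per_cycle=25, frame_rate=100.0)
    return generate_trial(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
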