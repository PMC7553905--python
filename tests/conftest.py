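import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _edf helper module

from microstates import GeneratorConfig, make_templates, simulate_recording


@pytest.fixture(scope="session")
def templates16():
    return make_templates(16, 4, seed=11)


@pytest.fixture(scope="session")
def small_recording(templates16):
    """Short 16-channel recording with planted 4-state structure."""
    cfg = GeneratorConfig(
        n_channels=16, n_maps=4, sfreq=250.0, epoch_length=2.0, n_epochs=2,
        snr=4.0, seed=11,
    )
    rec, gt = simulate_recording(cfg, templates16)
    return rec, gt, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
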