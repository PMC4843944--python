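import numpy as np
import pytest

from prestim import synthgen
from prestim.pipeline import EEGAnalysisConfig


@pytest.fixture(scope="session")
def fast_cfg() -> EEGAnalysisConfig:
    """Reduced-resolution analysis grid (2 Hz x 20 ms) used throughout the
    simulation tests; the 200 ms analysis window smooths the spectrogram well
    below this spacing, so cluster detection is unaffected."""
    return EEGAnalysisConfig(t_step_ms=20.0, f_step=2.0, n_perm=0)


@pytest.fixture(scope="session")
def default_subject():
    """One subject generated with all-default parameters, seed-fixed."""
    params = synthgen.EEGSimParams(seed=1234)
    return synthgen.generate_eeg_dataset(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160501)
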