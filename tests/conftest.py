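import numpy as np
import pytest

import eegpref
from eegpref import SimConfig, default_montage, generate_dataset, run_preprocessing


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset (3 subjects x 8 runs) with the default
    calibrated effects."""
    cfg = SimConfig(n_subjects=3, n_runs_per_subject=8, seed=11)
    recordings, truth = generate_dataset(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def small_segments(small_dataset):
    _, recordings, _ = small_dataset
    return run_preprocessing(recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_channel_recording(data, fs):
    """Wrap a 1-D signal as a one-channel recording."""
    m = eegpref.Montage(channel_names=("C3",), regions={})
    return eegpref.RawRecording(data=np.atleast_2d(data), fs=fs, montage=m)
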