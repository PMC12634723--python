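import numpy as np
import pytest

from mmdtkit import llgmn, synth
from mmdtkit.emg import build_training_samples
from mmdtkit.vision import BoardLayout


@pytest.fixture(scope="session")
def cal():
    return synth.default_calibration()


@pytest.fixture(scope="session")
def layout():
    return BoardLayout.default_grid()


@pytest.fixture(scope="session")
def trained_model(cal):
    """Hold/release classifier trained from synthetic calibration gestures."""
    samples = build_training_samples(
        synth.gen_training_recording("hold", cal, seed=11), "hold", cal)
    samples += build_training_samples(
        synth.gen_training_recording("release", cal, seed=12), "release", cal)
    return llgmn.train(samples, seed=0)
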