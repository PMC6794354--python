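import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from ecnet import EEGRecording, default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def noise_recording(montage, rng):
    """White-noise 29-channel recording, 12 s at 256 Hz."""
    data = rng.standard_normal((len(montage), 12 * 256)) * 10.0
    return EEGRecording(data, fs=256.0, labels=montage.channels)


def random_digraph(rng, n, p=0.4, weighted=False):
    A = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(A, 0.0)
    if weighted:
        A *= rng.uniform(0.2, 5.0, size=(n, n))
    return A
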