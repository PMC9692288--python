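import numpy as np
import pytest

from gaitnirs import (
    GroundTruth,
    Paradigm,
    default_montage,
    default_paradigm,
    generate_recording,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def paradigm():
    return default_paradigm()


@pytest.fixture(scope="session")
def short_paradigm():
    """4 blocks of 30+30 s: cheap but still block-designed."""
    return Paradigm(block_onsets=tuple(60.0 * b for b in range(4)))


@pytest.fixture(scope="session")
def small_recording(montage, short_paradigm):
    truth = GroundTruth.default(montage, seed=11)
    return generate_recording(montage, short_paradigm, truth, fs=10.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
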