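import numpy as np
import pytest

from bundlemotion.datatypes import MotionTruth, ScanConfig, StimulusSpec
from bundlemotion.synthgen import make_bundle_scene


@pytest.fixture(scope="session")
def scene():
    return make_bundle_scene(64, 64, seed=1)


@pytest.fixture(scope="session")
def scan():
    return ScanConfig()


@pytest.fixture(scope="session")
def tone():
    return StimulusSpec(kind="tone", frequency=220.0, level=80.0)


@pytest.fixture(scope="session")
def square_current():
    return StimulusSpec(kind="square_current", frequency=5.0, level=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def snr20_noise(scene):
    """Noise sd giving SNR 20 relative to the scene's intensity contrast."""
    return scene.image.std() / 20.0


def make_truth(**kw):
    defaults = dict(base_amplitude=98.0, tip_amplitude=90.0,
                    base_direction=(1.0, 0.0), tip_direction=(1.0, 0.0))
    defaults.update(kw)
    return MotionTruth(**defaults)
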