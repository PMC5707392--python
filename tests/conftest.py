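import numpy as np
import pytest

from spifftrack import PsfModel


@pytest.fixture
def noiseless_psf() -> PsfModel:
    """Deterministic rendering: no shot noise, no background noise."""
    return PsfModel(background_sd=0.0, shot_noise=False)


@pytest.fixture
def default_psf() -> PsfModel:
    return PsfModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
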