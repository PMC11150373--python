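import numpy as np
import pytest

from lraecg.synthetic import synth_beat_dataset


@pytest.fixture(scope="session")
def small_beats():
    """32 synthetic beats (8 per class), d=250, the overfit fixture."""
    return synth_beat_dataset(8, d=250, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
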