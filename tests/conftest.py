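import numpy as np
import pytest
from hypothesis import settings

import glomclass as gc

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """3 episodes of noise with one stimulus, 1 kHz."""
    return gc.Recording(
        traces=rng.normal(0.0, 1.0, size=(3, 2000)),
        sampling_rate=1000.0,
        mode="LCA",
        stim_times=[1.0],
        cell_id="fix01",
    )
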