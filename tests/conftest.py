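import numpy as np
import pytest

from lfpref import geometry, referencing


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_3x3():
    return geometry.build_grid(3, 3)


@pytest.fixture
def grid_10x10():
    return geometry.build_grid(10, 10)


@pytest.fixture
def small_recording(rng):
    """A tiny independent-noise recording: 2x2 grid, 30 trials."""
    grid = geometry.build_grid(2, 2)
    samples = rng.standard_normal((4, 30, 256))
    return referencing.EpochedRecording(
        samples=samples, sampling_rate=2000.0, grid=grid
    )
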