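import numpy as np
import pytest

from midgut4d.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, quiet movie: 40 cells, 20 frames, 7.5 min intervals."""
    return SimConfig(rng_seed=11, n_cells=40, n_frames=20)
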