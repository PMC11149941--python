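import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from petfuse.phantom import PhantomConfig, generate_control_volume
from petfuse.radiomics.discretize import DiscretizedROI
from petfuse.volume import Volume

SMALL_GRID = (20, 22, 18)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(grid_shape=SMALL_GRID, noise_sd=3.0, smoothness_mm=4.0)


@pytest.fixture(scope="session")
def small_control(small_config) -> Volume:
    return generate_control_volume(small_config, seed=7)


def make_disc(levels: np.ndarray) -> DiscretizedROI:
    """Wrap an integer level array (0 = outside mask) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int32)
    ng = max(int(levels.max()), 1)
    return DiscretizedROI(
        levels=levels,
        n_levels=ng,
        mask=levels > 0,
        bin_edges=np.arange(ng + 1, dtype=float),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
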