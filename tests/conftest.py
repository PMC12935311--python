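import numpy as np
import pytest

from voxelnav.terrain import MovementRules, TerrainMap


@pytest.fixture
def rules():
    return MovementRules()


@pytest.fixture
def flat_map():
    """10x8 flat obstacle-free terrain."""
    return TerrainMap(np.ones((10, 8), dtype=np.int64),
                      np.zeros((10, 8), dtype=bool))


@pytest.fixture
def ramp_map():
    """5x3 terrain rising one block per x step."""
    elevation = np.tile(np.arange(1, 6, dtype=np.int64)[:, None], (1, 3))
    return TerrainMap(elevation, np.zeros((5, 3), dtype=bool))


@pytest.fixture
def walled_map():
    """5x5 flat terrain with a wall forcing a detour.

    The wall occupies column x=2 except the top row, so paths from the
    left half to the right half must go through (2, 4).
    """
    obstructed = np.zeros((5, 5), dtype=bool)
    obstructed[2, :4] = True
    return TerrainMap(np.ones((5, 5), dtype=np.int64), obstructed)
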