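import numpy as np
import pytest

from tileshade.mosaic_io import Tile, TileMosaic
from tileshade.synthetic import make_clean_mosaic


@pytest.fixture
def clean_3x3():
    return make_clean_mosaic(3, 3, seed=11)


@pytest.fixture
def clean_stack():
    """3x3 grid, 2 identical focal layers."""
    return make_clean_mosaic(3, 3, n_layers=2, seed=12)


def constant_mosaic(levels, n_layers=1, tile=40, overlap=8, channels=("gray",)):
    """Mosaic of constant tiles; ``levels[(c, r, z)]`` or ``levels[r][c]``."""
    if isinstance(levels, (list, tuple)):
        levels = {(c, r, 0): levels[r][c]
                  for r in range(len(levels)) for c in range(len(levels[0]))}
    n_cols = max(p[0] for p in levels) + 1
    n_rows = max(p[1] for p in levels) + 1
    n_layers = max(n_layers, max(p[2] for p in levels) + 1)
    tiles = {
        pos: Tile(np.full((tile, tile, len(channels)), val, dtype=np.uint8), pos)
        for pos, val in levels.items()
    }
    return TileMosaic(tiles, n_cols, n_rows, n_layers, overlap, overlap,
                      channels, tile, tile)


@pytest.fixture
def constant_pair():
    """2x1 mosaic of constant tiles at 100 and 140."""
    return constant_mosaic([[100, 140]])
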