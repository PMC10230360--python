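import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cubeplay.shapes import GridItem, MazeItem


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_grid(cells, game="assembly"):
    return GridItem(rows=len(cells), cols=len(cells[0]), cells=[list(r) for r in cells], game=game)


@pytest.fixture
def comb_maze():
    """4x4 comb maze: open spine down column 0, fully open rows.

    15 open walls (a spanning tree); the corner-to-corner solution runs
    down the spine then along the bottom row (7 cells).
    """
    open_walls = set()
    for r in range(3):
        open_walls.add(frozenset({(r, 0), (r + 1, 0)}))
    for r in range(4):
        for c in range(3):
            open_walls.add(frozenset({(r, c), (r, c + 1)}))
    return MazeItem(dim=4, open_walls=open_walls, start=(0, 0), end=(3, 3))
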