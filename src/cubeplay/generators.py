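"""Autonomous item generators targeting a desired play complexity.

All games except Shape-Matching share one loop: draw a random item, and
while its complexity misses the target ``c_d`` by more than the tolerance
``e``, mutate a single feature of the item (a grid cell's shape, one
sequence entry, the traced path, or the maze end point), keeping the
mutation only when it moves the complexity toward the target.  After a run
of stagnant proposals the search restarts from a fresh random item.
Shape-Matching instead draws from a predefined pool of pattern families of
fixed complexity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import complexity as cx
from .shapes import (
    ALL_SHAPE_IDS,
    Color,
    Geometry,
    GridItem,
    MazeItem,
    PathItem,
    SequenceItem,
    ShapeMatchingItem,
    enumerate_surface_shapes,
    rotate_shape,
)

#: proposals without improvement before the search restarts from scratch
STAGNATION_LIMIT = 50


class InfeasibleTargetError(RuntimeError):
    """Target complexity not reached within the iteration budget.

    Carries the best item found so far and its complexity so callers can
    fall back to it or re-plan.
    """

    def __init__(self, message: str, best_item=None, best_breakdown=None):
        super().__init__(message)
        self.best_item = best_item
        self.best_breakdown = best_breakdown


@dataclass
class GeneratorConfig:
    """Target and search budget for :func:`generate_item`.

    ``dims`` is the grid dimension for Assembly/Spatial-Memory (2 or 3),
    the sequence length for Sequence-Memory, the node count for
    Path-Tracking, and the maze dimension for Maze.
    """

    c_d: float
    e: float = 0.25
    max_iterations: int = 5000
    dims: int = 3

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("tolerance e must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


# ---------------------------------------------------------------------------
# Random initial items


def random_grid(dims: int, rng: np.random.Generator, game: str = "assembly") -> GridItem:
    cells = rng.choice(ALL_SHAPE_IDS, size=(dims, dims)).tolist()
    return GridItem(rows=dims, cols=dims, cells=cells, game=game)


def random_sequence(length: int, rng: np.random.Generator) -> SequenceItem:
    return SequenceItem(shapes=rng.choice(ALL_SHAPE_IDS, size=length).tolist())


def generate_path(node_count: int, rng: np.random.Generator, grid_dim: int = 5) -> PathItem:
    """Uniform-restart self-avoiding walk of ``node_count`` nodes on the grid."""
    if not 2 <= node_count <= grid_dim * grid_dim:
        raise ValueError(f"node_count must be in [2, {grid_dim * grid_dim}]")
    while True:
        r, c = int(rng.integers(grid_dim)), int(rng.integers(grid_dim))
        nodes = [(r, c)]
        used = {(r, c)}
        while len(nodes) < node_count:
            r, c = nodes[-1]
            options = [
                (nr, nc)
                for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= nr < grid_dim and 0 <= nc < grid_dim and (nr, nc) not in used
            ]
            if not options:
                break  # walk trapped itself; restart
            nxt = options[int(rng.integers(len(options)))]
            nodes.append(nxt)
            used.add(nxt)
        if len(nodes) == node_count:
            return PathItem(nodes=nodes, grid_dim=grid_dim)


def generate_maze(dim: int, rng: np.random.Generator) -> MazeItem:
    """Perfect maze via randomized depth-first carving; solvable by construction.

    The carved open walls form a spanning tree of the cell grid (exactly
    dim**2 - 1 of them).  Start is the top-left cell; the end cell is drawn
    uniformly from the remaining cells.
    """
    if dim < 2:
        raise ValueError("maze dimension must be at least 2")
    open_walls: set[frozenset[tuple[int, int]]] = set()
    visited = {(0, 0)}
    stack = [(0, 0)]
    while stack:
        r, c = stack[-1]
        options = [
            (nr, nc)
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= nr < dim and 0 <= nc < dim and (nr, nc) not in visited
        ]
        if not options:
            stack.pop()
            continue
        nxt = options[int(rng.integers(len(options)))]
        open_walls.add(frozenset({(r, c), nxt}))
        visited.add(nxt)
        stack.append(nxt)
    cells = [(r, c) for r in range(dim) for c in range(dim) if (r, c) != (0, 0)]
    end = cells[int(rng.integers(len(cells)))]
    return MazeItem(dim=dim, open_walls=open_walls, start=(0, 0), end=end)


def _random_item(game: str, config: GeneratorConfig, rng: np.random.Generator):
    if game in ("assembly", "spatial_memory"):
        return random_grid(config.dims, rng, game=game)
    if game == "sequence_memory":
        return random_sequence(config.dims, rng)
    if game == "path_tracking":
        return generate_path(config.dims, rng)
    if game == "maze":
        return generate_maze(config.dims, rng)
    raise ValueError(f"no iterative generator for game {game!r}")


# ---------------------------------------------------------------------------
# Single-feature mutation


def mutate_item(item, rng: np.random.Generator):
    """Return a copy of the item with exactly one feature changed.

    The mutable feature is a grid cell's shape, one sequence entry, the
    traced path (redrawn with the same node count), or the maze end point
    (moved to an adjacent cell; walls stay fixed).
    """
    if isinstance(item, GridItem):
        r = int(rng.integers(item.rows))
        c = int(rng.integers(item.cols))
        choices = [s for s in ALL_SHAPE_IDS if s != item.cells[r][c]]
        cells = [row[:] for row in item.cells]
        cells[r][c] = int(choices[int(rng.integers(len(choices)))])
        return GridItem(rows=item.rows, cols=item.cols, cells=cells, game=item.game)
    if isinstance(item, SequenceItem):
        i = int(rng.integers(len(item.shapes)))
        choices = [s for s in ALL_SHAPE_IDS if s != item.shapes[i]]
        shapes = list(item.shapes)
        shapes[i] = int(choices[int(rng.integers(len(choices)))])
        return SequenceItem(shapes=shapes)
    if isinstance(item, PathItem):
        # redraw the path, adding or dropping one node when possible: the
        # degree distribution of a self-avoiding path is fixed by its node
        # count, so only the count moves the network complexity
        lo, hi = 2, item.grid_dim * item.grid_dim
        options = [v for v in (item.n_vertices - 1, item.n_vertices + 1) if lo <= v <= hi]
        v = options[int(rng.integers(len(options)))]
        return generate_path(v, rng, grid_dim=item.grid_dim)
    if isinstance(item, MazeItem):
        r, c = item.end
        options = [
            (nr, nc)
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= nr < item.dim and 0 <= nc < item.dim and (nr, nc) != item.start
        ]
        end = options[int(rng.integers(len(options)))]
        return MazeItem(dim=item.dim, open_walls=set(item.open_walls), start=item.start, end=end)
    raise TypeError(f"cannot mutate {type(item).__name__}")


def generate_item(
    game: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    params: cx.ComplexityParams = cx.DEFAULT_PARAMS,
):
    """Generate an item with |C_play - c_d| <= e for the given game.

    Greedy single-feature search with random restarts: a mutation is kept
    only when it strictly reduces the distance to the target; after
    ``STAGNATION_LIMIT`` rejected proposals the current item is replaced by
    a fresh random one.  Raises :class:`InfeasibleTargetError` (carrying
    the best item seen) when the budget is exhausted.

    Returns ``(item, breakdown)``.
    """
    if game == "shape_matching":
        raise ValueError("Shape-Matching items come from generate_shape_matching")
    item = _random_item(game, config, rng)
    bd = cx.play_complexity(item, params)
    best_item, best_bd = item, bd
    stagnant = 0
    for _ in range(config.max_iterations):
        gap = abs(bd.c_play - config.c_d)
        if gap <= config.e:
            return item, bd
        if abs(best_bd.c_play - config.c_d) > gap:
            best_item, best_bd = item, bd
        if stagnant >= STAGNATION_LIMIT:
            item = _random_item(game, config, rng)
            bd = cx.play_complexity(item, params)
            stagnant = 0
            continue
        candidate = mutate_item(item, rng)
        cand_bd = cx.play_complexity(candidate, params)
        if abs(cand_bd.c_play - config.c_d) < gap:
            item, bd = candidate, cand_bd
            stagnant = 0
        else:
            stagnant += 1
    if abs(bd.c_play - config.c_d) <= config.e:
        return item, bd
    raise InfeasibleTargetError(
        f"target c_d={config.c_d:.3f} (tol {config.e}) not reached for {game} "
        f"within {config.max_iterations} iterations; best |gap|="
        f"{abs(best_bd.c_play - config.c_d):.3f}",
        best_item=best_item,
        best_breakdown=best_bd,
    )


# ---------------------------------------------------------------------------
# Shape-Matching pattern pool

_TRIANGLES_A = tuple(s.id for s in enumerate_surface_shapes() if s.geometry is Geometry.TRIANGLE and s.color is Color.A)
_STRIPS_A = tuple(s.id for s in enumerate_surface_shapes() if s.geometry is Geometry.STRIP and s.color is Color.A)


def _color_swap(shape_id: int) -> int:
    s = next(x for x in enumerate_surface_shapes() if x.id == shape_id)
    other = next(
        x
        for x in enumerate_surface_shapes()
        if x.geometry is s.geometry and x.color is not s.color and x.orientation == s.orientation
    )
    return other.id


def _pool_patterns(level: int, rng: np.random.Generator) -> list[list[int]]:
    """Cell grid for one pattern family, seeded by a random shape draw.

    Families are built from a seed shape by fixed relative operations
    (rotations, color swaps), so every draw within a family has the same
    pair structure and hence the same configurational complexity.  Rotation
    families restrict the seed geometry so the rotations stay distinct.
    """
    any_id = int(rng.choice(ALL_SHAPE_IDS))
    strip = int(rng.choice(_STRIPS_A)) if rng.integers(2) == 0 else _color_swap(int(rng.choice(_STRIPS_A)))
    tri = int(rng.choice(_TRIANGLES_A)) if rng.integers(2) == 0 else _color_swap(int(rng.choice(_TRIANGLES_A)))
    r1 = lambda s: rotate_shape(s, 1)
    r2 = lambda s: rotate_shape(s, 2)
    r3 = lambda s: rotate_shape(s, 3)
    cs = _color_swap
    s = any_id
    if level == 0:  # 2x2 uniform — the easiest pattern: 4 identical shapes
        return [[s, s], [s, s]]
    if level == 1:  # 2x2 row color mirror
        return [[s, s], [cs(s), cs(s)]]
    if level == 2:  # 2x2 strip rotation checker
        return [[strip, r1(strip)], [r1(strip), strip]]
    if level == 3:  # 2x2 triangle rotation orbit
        return [[tri, r1(tri)], [r3(tri), r2(tri)]]
    if level == 4:  # 3x3 uniform
        return [[s] * 3 for _ in range(3)]
    if level == 5:  # 3x3 column color mirror
        return [[s, cs(s), s] for _ in range(3)]
    if level == 6:  # 3x3 color checkerboard
        return [
            [s, cs(s), s],
            [cs(s), s, cs(s)],
            [s, cs(s), s],
        ]
    if level == 7:  # 3x3 strip rotation rings
        return [
            [strip, r1(strip), strip],
            [r1(strip), strip, r1(strip)],
            [strip, r1(strip), strip],
        ]
    if level == 8:  # 3x3 triangle windmill
        return [
            [tri, r1(tri), r2(tri)],
            [r3(tri), tri, r1(tri)],
            [r2(tri), r3(tri), tri],
        ]
    if level == 9:  # 3x3 triangle orbit with color-swapped corners
        return [
            [cs(tri), r1(tri), cs(r2(tri))],
            [r3(tri), tri, r1(tri)],
            [cs(r2(tri)), r3(tri), cs(tri)],
        ]
    raise ValueError(f"invalid Shape-Matching level {level}; pool has levels 0-9")


N_SHAPE_MATCHING_LEVELS = 10


def generate_shape_matching(level: int, rng: np.random.Generator) -> ShapeMatchingItem:
    """Draw a Shape-Matching item from the pattern pool at the given level.

    Draws at one level differ in the concrete shapes but share the same
    play complexity; one uniformly chosen cell is hidden and its shape
    recorded as the answer.
    """
    cells = _pool_patterns(level, rng)
    grid = GridItem(rows=len(cells), cols=len(cells[0]), cells=cells, game="shape_matching")
    r = int(rng.integers(grid.rows))
    c = int(rng.integers(grid.cols))
    return ShapeMatchingItem(base=grid, missing_cell=(r, c), answer=grid.cells[r][c])
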