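"""Play-complexity measures for the six block games.

The scalar difficulty of an item, C_play, combines two terms:

* **compositional complexity** ``C_compos`` — information carried by the
  shapes themselves: each displayed face is one of ``m`` distinct glyphs in
  one of ``r`` distinct orientations, contributing ``log2(m * r)`` bits, so
  ``C_compos = sum_i log2(m_i * r_i)`` over the Q shapes of the item.  It
  depends only on the multiset of shapes, never on their arrangement.

* **configurational complexity** ``C_config`` — disorder of the
  arrangement, measured as the weighted Shannon entropy of a 14x14
  co-occurrence matrix of adjacent shape-id pairs (the GLCM construction,
  applied to shape ids rather than pixel intensities).  A pair of adjacent
  shapes that differ in *both* color and orientation weighs 2; every other
  pair weighs 1.

For the grid and sequence games the two terms are blended through a sigmoid
gate ``k(C_config)``:

    C_play = k(C_config) * C_compos + C_config

so that an item built from many high-symmetry shapes but arranged trivially
(large C_compos, C_config ~ 0) still comes out easy.  Shape-Matching uses
``C_play = C_config`` alone, summing the weighted entropies of three
direction-separated co-occurrence matrices (horizontal, vertical,
diagonal).  Path-Tracking uses the network complexity of the path graph
(entropy of the normalized vertex-degree distribution), and Maze combines
the maze-graph network complexity with two solution terms derived from the
A*-shortest path:

    C_play = 0.4 * (C_m + 10 * (C_s + C_l))

with ``C_s`` the mean of ``log2 s_i`` over the solution cells' degrees and
``C_l = log2 L`` for a solution of L cells.

The exact functional forms of ``C_compos``, the sigmoid gate, the weighted
entropy, ``C_s``/``C_l`` and the maze composition are this package's
adopted forms (see docs/methods.md); all are isolated behind
:class:`ComplexityParams` so alternative forms can be swapped in without
touching callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .shapes import (
    FOLD,
    GRID_GAMES,
    N_SHAPES,
    GridItem,
    MazeItem,
    PathItem,
    SequenceItem,
    ShapeMatchingItem,
    get_shape,
)

#: direction -> (delta_row, delta_col) for ordered pair extraction on a grid
DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (-1, -1)}

ALL_DIRECTIONS = (0, 45, 90, 135)


class InvalidDistributionError(ValueError):
    """Raised when an entropy argument is not a probability vector."""


class UnsolvableMazeError(ValueError):
    """Raised when no path exists between a maze's start and end cells."""


@dataclass
class ComplexityParams:
    """Tunable constants of the play-complexity measures.

    ``m_faces`` is the number of distinct glyphs available on a cube
    (6 when all faces differ).  ``sigmoid_alpha``/``sigmoid_beta`` set the
    slope and midpoint of the gate ``k``; the maze scale factors are fixed
    by the measure definition and should normally stay at 0.4 and 10.
    """

    m_faces: int = 6
    sigmoid_alpha: float = 1.0
    sigmoid_beta: float = 2.0
    maze_scale: float = 0.4
    maze_inner_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.sigmoid_alpha <= 0:
            raise ValueError("sigmoid_alpha must be positive")
        if self.m_faces < 1:
            raise ValueError("m_faces must be at least 1")


DEFAULT_PARAMS = ComplexityParams()


@dataclass
class ComplexityBreakdown:
    """C_play with its constituent terms.

    The maze terms ``c_m``, ``c_s``, ``c_l`` are populated only for maze
    items; for Shape-Matching ``c_play == c_config`` holds exactly.
    """

    c_play: float
    c_compos: float = 0.0
    c_config: float = 0.0
    k: float | None = None
    c_m: float | None = None
    c_s: float | None = None
    c_l: float | None = None

    def as_dict(self) -> dict:
        out = {"c_play": self.c_play, "c_compos": self.c_compos, "c_config": self.c_config}
        if self.k is not None:
            out["k"] = self.k
        if self.c_m is not None:
            out.update({"c_m": self.c_m, "c_s": self.c_s, "c_l": self.c_l})
        return out


@dataclass
class CoOccurrence:
    """Co-occurrence matrix of ordered adjacent shape-id pairs.

    ``f[a-1, b-1]`` counts extracted ordered pairs ``(a, b)`` over the
    requested directions; with ``circulant`` each grid line wraps around,
    closing it into a cycle.
    """

    f: np.ndarray
    directions: tuple[int, ...]
    circulant: bool

    @property
    def total(self) -> int:
        return int(self.f.sum())


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy -sum p_i log2 p_i in bits, with 0 log 0 = 0.

    ``p`` must be a probability vector (nonnegative, summing to 1 within
    1e-8); a uniform vector over n outcomes gives log2 n.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0 or np.any(arr < 0):
        raise InvalidDistributionError("probabilities must be nonnegative")
    if abs(arr.sum() - 1.0) > 1e-8:
        raise InvalidDistributionError(f"probabilities sum to {arr.sum()!r}, not 1")
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def compositional_complexity(
    item: GridItem | SequenceItem, params: ComplexityParams = DEFAULT_PARAMS
) -> float:
    """C_compos = sum over the item's shapes of log2(m_i * r_i), in bits.

    ``m_i`` is the number of distinct glyphs available on the cube showing
    shape i (``params.m_faces``) and ``r_i`` the shape's rotational fold.
    The value depends only on the multiset of shapes, not their positions.
    """
    ids = item.shapes if isinstance(item, SequenceItem) else item.shape_ids()
    return float(sum(math.log2(params.m_faces * get_shape(i).fold) for i in ids))


def _grid_lines(grid: list[list[int]], direction: int) -> list[list[int]]:
    """Cell-id sequences forming the maximal lines along one direction."""
    rows, cols = len(grid), len(grid[0])
    if direction == 0:
        return [list(r) for r in grid]
    if direction == 90:
        return [[grid[r][c] for r in range(rows)] for c in range(cols)]
    # diagonals: walk each anti-diagonal (45: up-right) or diagonal (135: up-left)
    dr, dc = DIRECTIONS[direction]
    lines = []
    starts = []
    if direction == 45:
        # start cells: left column plus bottom row
        starts = [(r, 0) for r in range(rows)] + [(rows - 1, c) for c in range(1, cols)]
    else:  # 135
        starts = [(r, cols - 1) for r in range(rows)] + [(rows - 1, c) for c in range(cols - 1)]
    for r0, c0 in starts:
        line, r, c = [], r0, c0
        while 0 <= r < rows and 0 <= c < cols:
            line.append(grid[r][c])
            r, c = r + dr, c + dc
        lines.append(line)
    return lines


def _line_pairs(line: list[int], circulant: bool) -> list[tuple[int, int]]:
    pairs = list(zip(line, line[1:]))
    if circulant and len(line) >= 2:
        pairs.append((line[-1], line[0]))
    return pairs


def extract_pairs(
    grid: GridItem, direction: int, circulant: bool = True
) -> list[tuple[int, int]]:
    """Ordered adjacent shape-id pairs along one direction of the grid.

    With ``circulant`` each line additionally contributes its wrap-around
    pair, e.g. the row (3, 5, 4) at 0 degrees yields (3, 5), (5, 4), (4, 3).
    Lines of a single cell contribute nothing.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    pairs: list[tuple[int, int]] = []
    for line in _grid_lines(grid.cells, direction):
        pairs.extend(_line_pairs(line, circulant))
    return pairs


def build_cooccurrence(
    pairs_or_grid: GridItem | Iterable[tuple[int, int]],
    directions: Sequence[int] = ALL_DIRECTIONS,
    circulant: bool = True,
) -> CoOccurrence:
    """Count ordered pairs into a 14x14 co-occurrence matrix.

    Accepts either a grid (pairs are extracted along ``directions``) or an
    already-extracted pair list.
    """
    if isinstance(pairs_or_grid, GridItem):
        pairs: list[tuple[int, int]] = []
        for d in directions:
            pairs.extend(extract_pairs(pairs_or_grid, d, circulant))
    else:
        pairs = list(pairs_or_grid)
    f = np.zeros((N_SHAPES, N_SHAPES), dtype=np.int64)
    for a, b in pairs:
        f[a - 1, b - 1] += 1
    return CoOccurrence(f=f, directions=tuple(directions), circulant=circulant)


def pair_weight(a: int, b: int) -> int:
    """2 if the two shapes differ in both color and orientation, else 1."""
    sa, sb = get_shape(a), get_shape(b)
    return 2 if (sa.color != sb.color and sa.orientation != sb.orientation) else 1


def _weight_matrix() -> np.ndarray:
    w = np.ones((N_SHAPES, N_SHAPES), dtype=float)
    for a in range(1, N_SHAPES + 1):
        for b in range(1, N_SHAPES + 1):
            w[a - 1, b - 1] = pair_weight(a, b)
    return w


WEIGHTS: np.ndarray = _weight_matrix()


def weighted_entropy(co: CoOccurrence, weights: np.ndarray = WEIGHTS) -> float:
    """Weighted entropy -sum w_ij p_ij log2 p_ij with p_ij = f_ij / sum f.

    An all-zero matrix (no extracted pairs, e.g. a 1x1 grid) contributes 0.
    """
    total = co.f.sum()
    if total == 0:
        return 0.0
    p = co.f / total
    mask = p > 0
    return float(-(weights[mask] * p[mask] * np.log2(p[mask])).sum())


def configurational_complexity(
    item: GridItem | SequenceItem | ShapeMatchingItem,
    params: ComplexityParams = DEFAULT_PARAMS,
) -> float:
    """C_config of an item, in bits.

    Grid games pool the ordered pairs of all four directions (0, 45, 90,
    135 degrees, circulant) into a single co-occurrence matrix and take its
    weighted entropy.  A sequence is treated as a single circulant 0-degree
    line.  Shape-Matching instead keeps three direction-separated matrices
    (horizontal, vertical, both diagonals pooled) and sums their weighted
    entropies.
    """
    if isinstance(item, ShapeMatchingItem):
        grid = item.base
        total = 0.0
        for dirs in ((0,), (90,), (45, 135)):
            total += weighted_entropy(build_cooccurrence(grid, directions=dirs))
        return total
    if isinstance(item, SequenceItem):
        pairs = _line_pairs(item.shapes, circulant=True)
        return weighted_entropy(build_cooccurrence(pairs))
    return weighted_entropy(build_cooccurrence(item, directions=ALL_DIRECTIONS))


def sigmoid_gate(c_config: float, params: ComplexityParams = DEFAULT_PARAMS) -> float:
    """k(C_config) = 1 / (1 + exp(-alpha * (C_config - beta))), in (0, 1)."""
    return float(1.0 / (1.0 + math.exp(-params.sigmoid_alpha * (c_config - params.sigmoid_beta))))


def play_complexity(
    item: GridItem | SequenceItem | ShapeMatchingItem | PathItem | MazeItem,
    params: ComplexityParams = DEFAULT_PARAMS,
) -> ComplexityBreakdown:
    """C_play of any item, with its breakdown.

    Dispatches on item type: grid/sequence items use the gated
    compositional + configurational blend; Shape-Matching uses C_config
    alone; paths use network complexity; mazes use the A*-based composite.
    """
    if isinstance(item, MazeItem):
        return maze_play_complexity(item, params)
    if isinstance(item, PathItem):
        return ComplexityBreakdown(c_play=path_network_complexity(item))
    if isinstance(item, ShapeMatchingItem):
        c_config = configurational_complexity(item, params)
        return ComplexityBreakdown(c_play=c_config, c_config=c_config)
    c_compos = compositional_complexity(item, params)
    c_config = configurational_complexity(item, params)
    k = sigmoid_gate(c_config, params)
    return ComplexityBreakdown(
        c_play=k * c_compos + c_config, c_compos=c_compos, c_config=c_config, k=k
    )


def path_network_complexity(path: PathItem) -> float:
    """Network complexity of a path: entropy of the normalized degree distribution.

    With degrees a_i over V vertices, p_i = a_i / sum a_j and the value is
    -sum p_i log2 p_i; all-equal degrees give log2 V.
    """
    degrees = path.degrees()
    return _degree_entropy(degrees)


def _degree_entropy(degrees: Sequence[int]) -> float:
    total = sum(degrees)
    if total == 0:
        return 0.0
    return shannon_entropy([d / total for d in degrees])


def maze_graph(maze: MazeItem) -> nx.Graph:
    """The maze as a graph: cells are nodes, open walls are edges."""
    g = nx.Graph()
    g.add_nodes_from((r, c) for r in range(maze.dim) for c in range(maze.dim))
    g.add_edges_from(tuple(w) for w in maze.open_walls)
    return g


def astar_shortest(maze: MazeItem) -> list[tuple[int, int]]:
    """Solve the maze with A* (Manhattan heuristic); stores and returns the path.

    The returned cell list includes both endpoints; its length defines L
    and the cells' maze-graph degrees define s_i.
    """
    g = maze_graph(maze)

    def manhattan(u, v):
        return abs(u[0] - v[0]) + abs(u[1] - v[1])

    try:
        path = nx.astar_path(g, maze.start, maze.end, heuristic=manhattan)
    except nx.NetworkXNoPath:
        raise UnsolvableMazeError(
            f"no path from {maze.start} to {maze.end} in {maze.dim}x{maze.dim} maze"
        ) from None
    maze.solution = path
    return path


def maze_play_complexity(
    maze: MazeItem, params: ComplexityParams = DEFAULT_PARAMS
) -> ComplexityBreakdown:
    """C_play = 0.4 * (C_m + 10 * (C_s + C_l)) for a solvable maze.

    ``C_m`` is the network complexity of the full maze graph (degree-
    distribution entropy), ``C_s`` the mean of log2 s_i over the L solution
    cells, and ``C_l = log2 L``.  Solves the maze first if needed.
    """
    if maze.solution is None:
        astar_shortest(maze)
    g = maze_graph(maze)
    c_m = _degree_entropy([d for _, d in g.degree()])
    s = maze.solution_degrees()
    L = len(s)
    c_s = float(np.mean([math.log2(si) for si in s])) if all(si > 0 for si in s) else 0.0
    c_l = math.log2(L) if L > 0 else 0.0
    c_play = params.maze_scale * (c_m + params.maze_inner_scale * (c_s + c_l))
    return ComplexityBreakdown(c_play=c_play, c_m=c_m, c_s=c_s, c_l=c_l)
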