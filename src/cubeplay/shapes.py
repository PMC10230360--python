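"""Cube-face taxonomy and item data structures for the six block games.

A play cube shows one of six black-and-white glyphs per face: a square, a
strip, or a triangle, in each of two color roles.  Under quarter-turn
rotations a square looks the same (1-fold), a strip has 2 distinct
appearances, and a triangle has 4, so the six faces yield
``2 * (1 + 2 + 4) = 14`` distinct surface appearances.  Every item used by
the games is built from these 14 appearance ids.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Geometry(str, enum.Enum):
    SQUARE = "square"
    STRIP = "strip"
    TRIANGLE = "triangle"


class Color(str, enum.Enum):
    A = "A"  # black-on-white role
    B = "B"  # white-on-black role


#: distinct appearances of each glyph under 90-degree rotation
FOLD = {Geometry.SQUARE: 1, Geometry.STRIP: 2, Geometry.TRIANGLE: 4}

#: games played on a rectangular grid of shapes
GRID_GAMES = ("assembly", "spatial_memory", "shape_matching")

ALL_GAMES = (
    "assembly",
    "shape_matching",
    "sequence_memory",
    "spatial_memory",
    "path_tracking",
    "maze",
)


class TaxonomyError(ValueError):
    """Raised for references to shape ids outside the 14-entry taxonomy."""


@dataclass(frozen=True)
class SurfaceShape:
    """One of the 14 distinct cube-face appearances.

    ``orientation`` counts quarter-turns and is always reduced modulo the
    geometry's symmetry fold, so ``orientation < fold`` holds by
    construction.
    """

    id: int
    geometry: Geometry
    color: Color
    orientation: int

    @property
    def fold(self) -> int:
        return FOLD[self.geometry]


def _build_taxonomy() -> tuple[SurfaceShape, ...]:
    # Canonical ordering: square < strip < triangle, color A < B,
    # orientation ascending.  Ids are 1-based and stable.
    shapes = []
    next_id = 1
    for geometry in (Geometry.SQUARE, Geometry.STRIP, Geometry.TRIANGLE):
        for color in (Color.A, Color.B):
            for orientation in range(FOLD[geometry]):
                shapes.append(SurfaceShape(next_id, geometry, color, orientation))
                next_id += 1
    return tuple(shapes)


_TAXONOMY: tuple[SurfaceShape, ...] = _build_taxonomy()
_BY_ID = {s.id: s for s in _TAXONOMY}
_BY_KEY = {(s.geometry, s.color, s.orientation): s for s in _TAXONOMY}

N_SHAPES = len(_TAXONOMY)
ALL_SHAPE_IDS = tuple(s.id for s in _TAXONOMY)


def enumerate_surface_shapes() -> list[SurfaceShape]:
    """Return the 14 distinct cube-face appearances.

    The appearances are obtained by rotating each of the six face glyphs
    (two colors each of square, strip, triangle) by 0, 90, 180, and 270
    degrees and keeping one entry per distinct look.  Ids are stable
    across calls.
    """
    return list(_TAXONOMY)


def get_shape(shape_id: int) -> SurfaceShape:
    """Look a shape up by its taxonomy id (1-14)."""
    try:
        return _BY_ID[shape_id]
    except KeyError:
        raise TaxonomyError(f"unknown shape id {shape_id!r}; valid ids are 1-14") from None


def rotate_shape(shape_id: int, quarter_turns: int) -> int:
    """Id of the appearance after rotating by ``quarter_turns`` * 90 degrees.

    Rotation acts on the orientation modulo the symmetry fold; rotating by
    a full multiple of the fold is the identity.
    """
    s = get_shape(shape_id)
    rotated = _BY_KEY[(s.geometry, s.color, (s.orientation + quarter_turns) % s.fold)]
    return rotated.id


# ---------------------------------------------------------------------------
# Item geometries


@dataclass
class GridItem:
    """A rows x cols arrangement of surface shapes (J in the measure notation)."""

    rows: int
    cols: int
    cells: list[list[int]]
    game: str = "assembly"

    def __post_init__(self) -> None:
        if self.game not in GRID_GAMES:
            raise ValueError(f"not a grid game: {self.game!r}")
        if len(self.cells) != self.rows or any(len(r) != self.cols for r in self.cells):
            raise ValueError("cells shape does not match rows x cols")
        for row in self.cells:
            for cid in row:
                get_shape(cid)  # validates

    @property
    def n_shapes(self) -> int:
        """Q, the total number of shapes in the item."""
        return self.rows * self.cols

    def shape_ids(self) -> list[int]:
        return [cid for row in self.cells for cid in row]


@dataclass
class ShapeMatchingItem:
    """A patterned grid with one cell hidden; the answer completes the pattern."""

    base: GridItem
    missing_cell: tuple[int, int]
    answer: int

    def __post_init__(self) -> None:
        r, c = self.missing_cell
        if not (0 <= r < self.base.rows and 0 <= c < self.base.cols):
            raise ValueError(f"missing_cell {self.missing_cell} outside grid")
        if self.base.cells[r][c] != self.answer:
            raise ValueError("answer does not match the shape at missing_cell")


@dataclass
class SequenceItem:
    """An ordered sequence of shapes shown one at a time (1 s per shape)."""

    shapes: list[int]
    display_seconds_per_shape: float = 1.0
    game: str = "sequence_memory"

    def __post_init__(self) -> None:
        if not self.shapes:
            raise ValueError("sequence must contain at least one shape")
        for cid in self.shapes:
            get_shape(cid)


@dataclass
class PathItem:
    """A self-avoiding connected path between two endpoint dots on a grid."""

    nodes: list[tuple[int, int]]
    grid_dim: int = 5
    game: str = "path_tracking"

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("path needs at least 2 nodes")
        seen = set()
        for r, c in self.nodes:
            if not (0 <= r < self.grid_dim and 0 <= c < self.grid_dim):
                raise ValueError(f"node ({r}, {c}) outside {self.grid_dim}x{self.grid_dim} grid")
            if (r, c) in seen:
                raise ValueError("path revisits a node")
            seen.add((r, c))
        for (r1, c1), (r2, c2) in zip(self.nodes, self.nodes[1:]):
            if abs(r1 - r2) + abs(c1 - c2) != 1:
                raise ValueError("consecutive path nodes must be grid-adjacent")

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.nodes[0], self.nodes[-1]

    @property
    def n_vertices(self) -> int:
        """V, the vertex count of the path graph."""
        return len(self.nodes)

    def degrees(self) -> list[int]:
        """Per-vertex degree list a_i of the path graph."""
        if len(self.nodes) == 1:
            return [0]
        return [1] + [2] * (len(self.nodes) - 2) + [1]


@dataclass
class MazeItem:
    """A dim x dim grid maze described by its set of open walls.

    ``open_walls`` holds unordered cell pairs whose shared wall is open; a
    perfect maze has exactly ``dim**2 - 1`` of them (a spanning tree).  The
    solver fills ``solution`` with the minimal cell path from start to end.
    """

    dim: int
    open_walls: set[frozenset[tuple[int, int]]]
    start: tuple[int, int]
    end: tuple[int, int]
    solution: list[tuple[int, int]] | None = None
    game: str = "maze"

    def __post_init__(self) -> None:
        for cell in (self.start, self.end):
            r, c = cell
            if not (0 <= r < self.dim and 0 <= c < self.dim):
                raise ValueError(f"cell {cell} outside {self.dim}x{self.dim} maze")
        for wall in self.open_walls:
            (r1, c1), (r2, c2) = tuple(wall)
            if abs(r1 - r2) + abs(c1 - c2) != 1:
                raise ValueError(f"open wall {set(wall)} does not join adjacent cells")

    def neighbors(self, cell: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = cell
        out = []
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < self.dim and 0 <= nc < self.dim:
                if frozenset({cell, (nr, nc)}) in self.open_walls:
                    out.append((nr, nc))
        return out

    @property
    def solution_length(self) -> int | None:
        """L, the number of cells on the solved shortest path (endpoints included)."""
        return None if self.solution is None else len(self.solution)

    def solution_degrees(self) -> list[int]:
        """s_i, the maze-graph degree of each cell on the solution path."""
        if self.solution is None:
            raise ValueError("maze has not been solved yet")
        return [len(self.neighbors(cell)) for cell in self.solution]
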