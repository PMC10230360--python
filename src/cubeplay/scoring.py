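"""Fixed and adaptive point tables for the six games.

Fixed scoring awards integer points from correctness, item size, completion
time, and (for the two path games) whether the traced path was the
shortest.  Time bands are half-open, inclusive on the right edge of each
printed band: "within 15 seconds" means [0, 15] and "between 15 and 30"
means (15, 30].  Anything not matching a band scores 0.

Adaptive sessions deduct points for items served after misses: a correct
answer on an item regenerated at the same complexity (after one miss)
scores one point less than the fixed table, and a correct answer on the
easier item generated after two consecutive misses scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .shapes import ALL_GAMES, GridItem, MazeItem, PathItem, SequenceItem, ShapeMatchingItem

#: games scored on correctness alone (the recorded time is ignored)
UNTIMED_GAMES = ("shape_matching", "sequence_memory", "spatial_memory")


@dataclass
class Outcome:
    """One answered item as the scorer sees it."""

    game: str
    correct: bool
    completion_time: float = 0.0
    item_dims: tuple[int, int] | None = None  # (rows, cols) for Assembly
    took_shortest: bool = False  # Path-Tracking / Maze only

    def __post_init__(self) -> None:
        if self.game not in ALL_GAMES:
            raise ValueError(f"unknown game {self.game!r}")
        if self.completion_time < 0:
            raise ValueError("completion_time must be nonnegative")


@dataclass
class AdaptiveScoreContext:
    """Why the current adaptive item was generated; the flags are exclusive."""

    repeated_same_complexity: bool = False
    after_two_misses: bool = False

    def __post_init__(self) -> None:
        if self.repeated_same_complexity and self.after_two_misses:
            raise ValueError("context flags are mutually exclusive")


def _banded(t: float, bands: list[tuple[float, int]]) -> int:
    """Points for the first band whose right edge is >= t (bands sorted)."""
    for upper, points in bands:
        if t <= upper:
            return points
    return 0


def score_fixed(outcome: Outcome) -> int:
    """Points under the fixed-version tables.

    Assembly: 2x2 gives 3/2 points at <=15 s / (15, 30] s; 3x3 gives 4/3/2
    points at <=30 / (30, 40] / (40, 60] s.  Shape-Matching,
    Sequence-Memory, and Spatial-Memory give 2 points per correct answer.
    Path-Tracking: shortest path gives 4/2/1 at <=20 / (20, 40] /
    (40, 80] s, a correct non-shortest path 2/1 at <=20 / (20, 40] s.
    Maze: shortest gives 4/2/1 at <=10 / (10, 20] / (20, 40] s,
    non-shortest 2/1 at <=10 / (10, 20] s.  Everything else scores 0.
    """
    if not outcome.correct:
        return 0
    t = outcome.completion_time
    game = outcome.game
    if game in UNTIMED_GAMES:
        return 2
    if game == "assembly":
        if outcome.item_dims is None:
            raise ValueError("Assembly outcomes need item_dims")
        if outcome.item_dims[0] * outcome.item_dims[1] <= 4:
            return _banded(t, [(15, 3), (30, 2)])
        return _banded(t, [(30, 4), (40, 3), (60, 2)])
    if game == "path_tracking":
        if outcome.took_shortest:
            return _banded(t, [(20, 4), (40, 2), (80, 1)])
        return _banded(t, [(20, 2), (40, 1)])
    if game == "maze":
        if outcome.took_shortest:
            return _banded(t, [(10, 4), (20, 2), (40, 1)])
        return _banded(t, [(10, 2), (20, 1)])
    raise ValueError(f"unknown game {game!r}")


def score_adaptive(outcome: Outcome, context: AdaptiveScoreContext | None = None) -> int:
    """Points in adaptive mode, applying the post-miss deductions.

    A correct answer on a same-complexity regeneration scores the fixed
    points minus 1 (floored at 0); a correct answer right after a two-miss
    midpoint revert scores exactly 1; otherwise the fixed table applies.
    """
    if context is None:
        context = AdaptiveScoreContext()
    if not outcome.correct:
        return 0
    if context.after_two_misses:
        return 1
    base = score_fixed(outcome)
    if context.repeated_same_complexity:
        return max(base - 1, 0)
    return base


def outcome_for_item(game: str, item, correct: bool, completion_time: float) -> Outcome:
    """Build an Outcome from a game item and a response.

    Simulated and interactive responders report correctness and time only;
    a correct answer in the path games is taken to be the shortest path
    (the complexity measures are defined on the shortest solution).
    """
    dims = None
    if isinstance(item, GridItem):
        dims = (item.rows, item.cols)
    elif isinstance(item, ShapeMatchingItem):
        dims = (item.base.rows, item.base.cols)
    shortest = correct and game in ("path_tracking", "maze")
    return Outcome(
        game=game,
        correct=correct,
        completion_time=completion_time,
        item_dims=dims,
        took_shortest=shortest,
    )
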