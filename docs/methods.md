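# Methods

This note documents the models implemented by `cubeplay`, the constants they
use, and the design decisions taken where more than one reasonable choice
existed.

## The setting

The package models a tabletop cognitive-assessment system built on a set of
play cubes.  Each cube face carries one of six black-and-white glyphs — a
square, a strip, or a triangle, in each of two color roles.  Six games are
played with the cubes: three pattern games on grids (Assembly,
Spatial-Memory, Shape-Matching), one sequence-recall game
(Sequence-Memory), and two single-cube tracing games (Path-Tracking, Maze).
Every game item has a scalar *play complexity* `C_play` that estimates its
difficulty, and the adaptive engine sequences item complexities from a
player's correctness record.  The package implements the computational core
only — complexity measures, item generators, the difficulty staircase,
scoring, and simulated examinees — not the camera pipeline or any hardware.

## Face taxonomy

Under 90° rotation a square glyph has a single appearance (1-fold), a strip
two (2-fold), and a triangle four (4-fold).  With two colors of each
geometry, the six faces yield `2·(1+2+4) = 14` distinct surface
appearances.  Ids 1–14 are assigned in a fixed canonical order (square <
strip < triangle, color A < B, orientation ascending); any permutation of
ids would serve equally as long as the (geometry, color, orientation)
metadata is right, and all measures depend only on that metadata.

## Play-complexity measures

### Compositional complexity

`C_compos = Σ_i log2(m_i · r_i)` over the `Q` shapes of an item, where
`m_i` is the number of distinct glyphs available on a cube (6 by default)
and `r_i` the shape's rotational fold.  This is the Shannon information of
independently choosing each displayed face and its orientation; it reduces
to `H = log2 n` per uniform choice and is invariant under any rearrangement
of the same shapes.

### Configurational complexity

Arrangement disorder is measured with a co-occurrence matrix over shape
ids (the GLCM construction, applied to symbols rather than gray levels).
All ordered adjacent pairs along the 0°, 45°, 90°, and 135° directions are
extracted from the grid, each line closed circulantly (the row `(3, 5, 4)`
contributes `(3,5), (5,4), (4,3)`), and counted into a 14×14 matrix `f`.
The weighted entropy

    C_config = − Σ_ij w_ij · p_ij · log2 p_ij,   p_ij = f_ij / Σf

uses weight `w_ij = 2` when the two shapes differ in *both* color and
orientation and `1` otherwise.  Sequences are treated as a single circulant
0° line.  Assembly and Spatial-Memory pool all four directions into one
matrix; Shape-Matching keeps three direction-separated matrices
(horizontal, vertical, both diagonals pooled) and sums their weighted
entropies.

### Composition

For Assembly, Sequence-Memory, and Spatial-Memory:

    C_play = k(C_config) · C_compos + C_config,
    k(x) = 1 / (1 + exp(−α (x − β))),  α = 1.0, β = 2.0 by default.

The sigmoid gate suppresses the compositional term for near-uniform
arrangements: a 3×3 item of nine identical triangles has `C_compos ≈ 41`
bits but `C_play ≈ 2.8`.  Shape-Matching uses `C_play = C_config` alone,
since a larger shape inventory does not make a one-missing-piece pattern
harder.

The gated-sum composition, the exact `C_compos` form, and the weighted
entropy above are this package's **adopted forms**: they satisfy the
qualitative contracts the design fixes (uniform-case entropy, the
equal-composition/different-configuration distinction, gate behaviour)
but other forms with the same properties exist.  All constants live in
`ComplexityParams` so a different form can be swapped in without touching
callers.

### Path-Tracking

The traced path is scored by network complexity: the Shannon entropy of
the normalized vertex-degree distribution, `p_i = a_i / Σ a_j`.  For a
self-avoiding path this is a strictly increasing function of the node
count alone (interior degrees are all 2), which is why the generator and
the fixed schedules vary difficulty through the number of nodes.

### Maze

    C_play = 0.4 · (C_m + 10 · (C_s + C_l))

`C_m` is the network complexity of the full maze graph (cells as vertices,
open walls as edges).  The maze is solved with A* (Manhattan heuristic;
verified against breadth-first search), giving a shortest solution of `L`
cells with maze-graph degrees `s_i`.  The solution terms are the adopted
forms `C_s = (1/L) Σ log2 s_i` (mean branching along the solution, ≤ 1 in
a pure corridor) and `C_l = log2 L`.  The 0.4 factor scales the total into
the range of the other games' complexities and the inner 10 balances the
solution terms against `C_m`; both are configurable but fixed by default.
`L` counts cells including both endpoints; a degenerate start-equals-end
maze has `L = 1` and `C_l = 0`.

## Item generators

All games except Shape-Matching share a target-complexity loop: draw a
random item, then repeatedly mutate a single feature — one grid cell's
shape, one sequence entry, the traced path (redrawn, with the node count
allowed to move by one), or the maze end point (walls fixed) — keeping a
mutation only when it strictly reduces `|C_play − C_d|`, until the
tolerance `e` is met.  The search policy (greedy accept, restart from a
fresh random item after 50 stagnant proposals, default budget 5,000
iterations, default `e = 0.25`) is this package's choice; the loop's
input/output contract `|C_play − C_d| ≤ e` is the fixed part.  An
exhausted budget raises an infeasibility error carrying the best item
found, which callers such as the cohort simulator may use as the nearest
achievable item.

Mazes are carved with randomized depth-first search, producing a perfect
maze (a spanning tree: exactly `dim² − 1` open walls, unique solution
path).  Paths are uniform-restart self-avoiding walks on the 5×5 grid.

Shape-Matching draws from a predefined pool of 10 pattern families of
increasing configurational complexity (uniform fill, color mirrors, a
checkerboard, strip- and triangle-rotation orbits, and mixed
rotation/color patterns).  Each family fixes the *relations* between cells
(rotations and color swaps of a randomly drawn seed shape, with the seed
geometry restricted so rotations stay distinct), so every draw at a level
shares the same `C_play` while the concrete shapes differ.  One uniformly
chosen cell is hidden and recorded as the answer.

## Adaptive engine

The difficulty staircase starts at a predefined low complexity.  A correct
answer raises the target by `up_step` (default 0.5, capped at the
ceiling); one miss repeats the same complexity; two consecutive misses
revert the target to the midpoint between the latest correctly answered
complexity and the current one (anchored at the start complexity before
any correct answer).  A session ends on a correct answer at the ceiling,
when the magnitude of a difficulty change (climb or revert) drops below
`min_step` (default 0.05), or at a safety cap of `max_items` (default 25).
The same-complexity repeat after a single miss is not a difficulty change
and never triggers the step criterion — otherwise every first miss would
end the session.  After a miss is recovered, climbing resumes with the
full `up_step`.  State updates use the complexity the generator actually
achieved, not the requested target, since the generator only guarantees
its tolerance.

The midpoint rule contracts the gap between the anchors whenever misses
alternate with corrects, so the staircase converges; the item cap bounds
every other trajectory.  With a deterministic threshold responder
(correct iff `C_play < θ`) the settled complexity recovers `θ` to within
`2·up_step` across seeds.

## Scoring

Fixed-mode point tables (points by completion time `t`, correct answers
only; everything else scores 0):

| game | condition | bands |
|---|---|---|
| Assembly 2×2 | — | 3 (t ≤ 15 s), 2 (15 < t ≤ 30) |
| Assembly 3×3 | — | 4 (t ≤ 30), 3 (30 < t ≤ 40), 2 (40 < t ≤ 60) |
| Shape-/Sequence-/Spatial-Memory | untimed | 2 per correct answer |
| Path-Tracking | shortest | 4 (t ≤ 20), 2 (20 < t ≤ 40), 1 (40 < t ≤ 80) |
| Path-Tracking | correct, not shortest | 2 (t ≤ 20), 1 (20 < t ≤ 40) |
| Maze | shortest | 4 (t ≤ 10), 2 (10 < t ≤ 20), 1 (20 < t ≤ 40) |
| Maze | correct, not shortest | 2 (t ≤ 10), 1 (10 < t ≤ 20) |

Band membership is half-open, inclusive on the right edge ("within 15
seconds" = `[0, 15]`, "between 15 and 30" = `(15, 30]`); the boundary
convention is a package decision, as the bands are printed without one.

Adaptive deductions: a correct answer on an item regenerated at the same
complexity (after one miss) scores one point less than the fixed table,
floored at 0; a correct answer on the easier item generated after two
consecutive misses scores exactly 1 point regardless of the table.  The
deduction is plain subtraction — it does not interact further with the
time bands.

## Simulated examinees

A player is a logistic response model on the complexity scale:

    P(correct) = 1 / (1 + exp(slope · (C_play − ability)))
    time = base_time + time_slope · C_play + Normal(0, sd), truncated at 0

Defaults: slope 1.5 per complexity unit, base time 5 s, 2 s per complexity
unit, noise sd 1 s.  The linear-in-complexity time model and the logistic
are stand-ins for human behaviour, chosen to carry the two signs the
measures are designed to induce (accuracy falls, time rises with
complexity); they are isolated behind `PlayerModel`.

The validity re-enactment runs cohorts of 38 players (the fixed-schedule
study-arm size; 42 for adaptive arms) on 12-item fixed schedules spanning
each game's attainable complexity range (targets on an even grid between
the 5th and 95th percentiles of 60 random probes; node-count sweep for
Path-Tracking), with abilities drawn uniformly over the middle 80% of the
schedule's range.  Per-item mean correctness and mean completion time are
correlated with `C_play` by Spearman rank correlation (average ranks for
ties, two-sided p, 95% Fisher-transform CI).  In adaptive mode each
presented item is its own observation.

What the simulation does *not* model: learning and fatigue across items,
response-time distributions of real examinees (no heavy tails), memory
strategies — in particular the way symmetric Spatial-Memory patterns are
easier to memorize than their configurational entropy suggests.  A passing
sign-pattern test therefore shows the measures and harness are internally
coherent, not that they are valid for humans.

## Numerical conventions

- Entropies in bits (`log2`) throughout; `0·log 0 ≡ 0`.
- Probability vectors are validated to sum to 1 within 1e-8.
- An empty co-occurrence matrix (e.g. a 1×1 grid) has weighted entropy 0.
- Grid cells are 0-based `(row, col)`, row-major; item JSON stores cells as
  a row-major flat list.
- All randomness flows through an explicit `numpy.random.Generator`; equal
  seeds give bit-identical items, sessions, and logs.

## Problem sizes

Default test and simulation sizes: 3×3 Assembly grids, 2×2 Spatial-Memory,
length-5 sequences, 8-node initial paths on the 5×5 grid, 6×6 mazes;
cohorts of 38 players on 12-item schedules with 100 seeded replicates;
1,000 generator draws per game in the tolerance sweep; 200 mazes in the
A*-vs-BFS equivalence check.

## Known limitations

- Spatial-Memory receives no symmetry discount, although symmetric
  patterns are empirically easier to memorize; the measure will overrate
  such items.
- Maze mutation moves only the end point; wall structure changes come from
  search restarts, so braided (multi-solution) mazes never occur.
- The adaptive engine is a rule-based staircase, not an item-response-
  theory ability estimator; `final_c` is a convergence point, not a scaled
  score.
- Scoring tables are the bench versions; no norming or standardization is
  provided.
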