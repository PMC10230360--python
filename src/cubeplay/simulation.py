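"""Synthetic examinees and the in-silico complexity-validity analysis.

Human participants are replaced by a logistic response model: a player of
ability theta (on the play-complexity scale) answers an item of complexity
C correctly with probability ``1 / (1 + exp(slope * (C - theta)))``, and
takes ``base_time + time_slope * C`` seconds plus truncated-normal noise.
Higher complexity therefore lowers expected accuracy and raises expected
completion time, the qualitative pattern the measures are meant to induce.

:func:`run_cohort` re-enacts the validity analysis: a cohort plays a fixed
item schedule (or adaptive sessions), per-item mean correctness and mean
completion time are aggregated, and Spearman rank correlations of C_play
against both indicators are computed with Fisher-transform confidence
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import adaptive as ad
from . import complexity as cx
from . import generators as gen
from . import scoring


@dataclass
class PlayerModel:
    """Logistic-accuracy, linear-time synthetic examinee.

    ``ability`` is on the complexity scale (items at this complexity are
    answered correctly half the time); ``slope`` is the discrimination of
    the logistic (per complexity unit); time parameters are in seconds and
    seconds per complexity unit.
    """

    ability: float
    slope: float = 1.5
    base_time: float = 5.0
    time_slope: float = 2.0
    time_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if min(self.base_time, self.time_slope, self.time_noise_sd) < 0:
            raise ValueError("time parameters must be nonnegative")


def p_correct(player: PlayerModel, c_play: float) -> float:
    """P(correct) = 1 / (1 + exp(slope * (C_play - ability)))."""
    return float(1.0 / (1.0 + math.exp(player.slope * (c_play - player.ability))))


def respond(
    player: PlayerModel, breakdown: cx.ComplexityBreakdown, rng: np.random.Generator
) -> tuple[bool, float]:
    """Draw one (correct, completion_time) response to an item."""
    correct = bool(rng.random() < p_correct(player, breakdown.c_play))
    t = player.base_time + player.time_slope * breakdown.c_play
    t += float(rng.normal(0.0, player.time_noise_sd)) if player.time_noise_sd > 0 else 0.0
    return correct, max(t, 0.0)


def spearman_ci(x, y, level: float = 0.95) -> tuple[float, float, float, float]:
    """Spearman rank correlation with two-sided p and a Fisher-transform CI.

    Ties get average ranks.  Raises on zero variance in either vector
    (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    r = float(r)
    n = x.size
    if abs(r) >= 1.0 or n <= 3:
        return r, float(p), r, r
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return r, float(p), float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


@dataclass
class CohortResult:
    """Per-item aggregates and the two validity correlations for one game."""

    game: str
    mode: str
    n_players: int
    c_play: list[float]
    mean_correctness: list[float]
    mean_time: list[float]
    r_time: float
    p_time: float
    ci_time: tuple[float, float]
    r_correct: float | None
    p_correct: float | None
    ci_correct: tuple[float, float] | None
    correctness_varies: bool = True


def default_cohort(
    schedule_c: list[float], n_players: int, rng: np.random.Generator
) -> list[PlayerModel]:
    """Players with abilities uniform over the mid-80% of the schedule's range."""
    lo, hi = min(schedule_c), max(schedule_c)
    span = hi - lo
    a, b = lo + 0.1 * span, hi - 0.1 * span
    return [PlayerModel(ability=float(rng.uniform(a, b))) for _ in range(n_players)]


def fixed_schedule(
    game: str,
    n_items: int,
    rng: np.random.Generator,
    *,
    dims: int | None = None,
    params: cx.ComplexityParams = cx.DEFAULT_PARAMS,
) -> list[tuple[object, cx.ComplexityBreakdown]]:
    """A graded item schedule spanning the game's attainable complexity range.

    Probes the range with random draws, then generates one item per target
    on an even grid between the observed low and high complexities —
    emulating a hand-picked fixed item set of increasing difficulty.
    """
    if game == "shape_matching":
        levels = np.linspace(0, gen.N_SHAPE_MATCHING_LEVELS - 1, n_items).round().astype(int)
        out = []
        for lv in levels:
            item = gen.generate_shape_matching(int(lv), rng)
            out.append((item, cx.play_complexity(item, params)))
        return out
    if game == "path_tracking":
        # path complexity is a function of the node count alone, so a
        # graded schedule is a graded sweep of node counts
        counts = np.unique(np.linspace(3, 20, n_items).round().astype(int))
        out = []
        for v in counts:
            item = gen.generate_path(int(v), rng)
            out.append((item, cx.play_complexity(item, params)))
        return out
    dims = dims if dims is not None else _default_dims(game)
    probes = [
        cx.play_complexity(gen._random_item(game, gen.GeneratorConfig(c_d=0, dims=dims), rng), params).c_play
        for _ in range(60)
    ]
    # span the inner quantiles: the extremes of the probed range are rare
    # single draws the greedy search cannot reliably reach
    lo, hi = np.quantile(probes, [0.05, 0.95])
    targets = np.linspace(lo, hi, n_items)
    out = []
    for t in targets:
        cfg = gen.GeneratorConfig(c_d=float(t), dims=dims)
        try:
            out.append(gen.generate_item(game, cfg, rng, params))
        except gen.InfeasibleTargetError as exc:
            out.append((exc.best_item, exc.best_breakdown))
    return out


def _default_dims(game: str) -> int:
    return {
        "assembly": 3,
        "spatial_memory": 2,
        "sequence_memory": 5,
        "path_tracking": 8,
        "maze": 6,
    }.get(game, 3)


def run_cohort(
    game: str,
    mode: str,
    n_players: int,
    rng: np.random.Generator,
    *,
    item_schedule: list[tuple[object, cx.ComplexityBreakdown]] | None = None,
    players: list[PlayerModel] | None = None,
    n_items: int = 12,
    params: cx.ComplexityParams = cx.DEFAULT_PARAMS,
) -> CohortResult:
    """Simulate a cohort and correlate C_play with the performance indicators.

    Fixed mode presents the same schedule to every player and aggregates
    per item; adaptive mode runs one adaptive session per player and pools
    every presented item as its own observation.  Expected signs: positive
    for mean completion time, negative for mean correctness where
    correctness varies.
    """
    if n_players < 3:
        raise ValueError("need at least 3 players for a correlation")
    if mode not in ("fixed", "adaptive"):
        raise ValueError(f"mode must be 'fixed' or 'adaptive', got {mode!r}")

    if mode == "fixed":
        if item_schedule is None:
            item_schedule = fixed_schedule(game, n_items, rng, params=params)
        c_play = [bd.c_play for _, bd in item_schedule]
        if players is None:
            players = default_cohort(c_play, n_players, rng)
        correct = np.zeros((n_players, len(item_schedule)))
        times = np.zeros_like(correct)
        for i, player in enumerate(players):
            for j, (_, bd) in enumerate(item_schedule):
                ok, t = respond(player, bd, rng)
                correct[i, j] = ok
                times[i, j] = t
        mean_correct = correct.mean(axis=0).tolist()
        mean_time = times.mean(axis=0).tolist()
    else:
        schedule_probe = fixed_schedule(game, n_items, rng, params=params)
        probe_c = [bd.c_play for _, bd in schedule_probe]
        if players is None:
            players = default_cohort(probe_c, n_players, rng)
        lo, hi = min(probe_c), max(probe_c)
        acfg = ad.AdaptiveConfig(start_c=lo, ceiling_c=max(hi, lo + 1.0))
        gcfg = gen.GeneratorConfig(c_d=lo, dims=_default_dims(game))
        def nearest_item(target_c):
            # midpoint targets can fall between the discrete complexities a
            # small item space attains; present the closest achievable item
            cfg = gen.GeneratorConfig(
                c_d=target_c, e=gcfg.e, max_iterations=gcfg.max_iterations, dims=gcfg.dims
            )
            try:
                return gen.generate_item(game, cfg, rng, params)
            except gen.InfeasibleTargetError as exc:
                return exc.best_item, exc.best_breakdown

        c_play, mean_correct, mean_time = [], [], []
        for player in players:
            log = ad.run_session(
                game,
                lambda item, bd: respond(player, bd, rng),
                acfg,
                rng,
                item_provider=nearest_item,
                params=params,
            )
            for rec in log.records:
                c_play.append(rec.c_play)
                mean_correct.append(float(rec.correct))
                mean_time.append(rec.completion_time)

    r_t, p_t, lo_t, hi_t = spearman_ci(c_play, mean_time)
    varies = np.ptp(mean_correct) > 0
    if varies:
        r_c, p_c, lo_c, hi_c = spearman_ci(c_play, mean_correct)
        cc = (r_c, p_c, (lo_c, hi_c))
    else:
        cc = (None, None, None)
    return CohortResult(
        game=game,
        mode=mode,
        n_players=n_players,
        c_play=list(map(float, c_play)),
        mean_correctness=list(map(float, mean_correct)),
        mean_time=list(map(float, mean_time)),
        r_time=r_t,
        p_time=p_t,
        ci_time=(lo_t, hi_t),
        r_correct=cc[0],
        p_correct=cc[1],
        ci_correct=cc[2],
        correctness_varies=bool(varies),
    )
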