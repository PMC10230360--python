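"""Rule-based dynamic-difficulty engine sequencing item complexities.

The session starts at a predefined low complexity.  A correct answer moves
the target up by a fixed step (capped at the ceiling); a single incorrect
answer repeats the same complexity; two consecutive incorrect answers
revert the target to the midpoint between the latest correctly answered
complexity and the current incorrectly answered one.  The session ends on
a correct answer at the ceiling, when the magnitude of a difficulty
*change* (climb or midpoint revert) falls below ``min_step``, or at a
safety cap on the number of items.  The midpoint rule contracts the gap
between the anchor complexities, so every session terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import complexity as cx
from . import generators as gen
from . import scoring


class SessionTerminatedError(RuntimeError):
    """Raised when a terminated adaptive state receives another update."""


@dataclass
class AdaptiveConfig:
    """Staircase parameters: start/ceiling complexities, step sizes, item cap."""

    start_c: float
    ceiling_c: float
    up_step: float = 0.5
    min_step: float = 0.05
    max_items: int = 25

    def __post_init__(self) -> None:
        if not self.start_c < self.ceiling_c:
            raise ValueError("start_c must be below ceiling_c")
        if not self.up_step > self.min_step > 0:
            raise ValueError("need up_step > min_step > 0")


@dataclass
class ItemRecord:
    """One presented item: its complexity, the response, and the score."""

    index: int
    target_c: float
    c_play: float
    correct: bool
    completion_time: float
    score: int
    breakdown: dict = field(default_factory=dict)


@dataclass
class AdaptiveState:
    """Bookkeeping of the difficulty staircase.

    ``current_c`` is the complexity of the item being answered,
    ``last_correct_c`` the complexity of the latest correctly answered item
    (anchored at the start complexity before any correct answer), and
    ``step`` the signed difficulty change decided by the most recent
    correct-answer climb or two-miss midpoint revert (``None`` until one
    occurs; a single-miss repeat leaves it untouched).
    """

    current_c: float
    last_correct_c: float
    next_c: float
    step: float | None = None
    consecutive_incorrect: int = 0
    just_reverted: bool = False
    current_at_ceiling: bool = False
    at_ceiling_correct: bool = False
    n_items: int = 0
    terminated: bool = False


def initial_state(config: AdaptiveConfig) -> AdaptiveState:
    return AdaptiveState(
        current_c=config.start_c, last_correct_c=config.start_c, next_c=config.start_c
    )


def update(state: AdaptiveState, correct: bool, config: AdaptiveConfig) -> AdaptiveState:
    """Apply one response and return the state with the next target complexity.

    Correct: climb by ``up_step``, capped at the ceiling.  First miss:
    repeat the same complexity.  Second consecutive miss: revert to the
    midpoint between the latest correct complexity and the current one.
    """
    if state.terminated:
        raise SessionTerminatedError("cannot update a terminated session")
    s = replace(state, n_items=state.n_items + 1, just_reverted=False)
    if correct:
        if state.current_at_ceiling or state.current_c >= config.ceiling_c - 1e-12:
            s.at_ceiling_correct = True
        target = min(state.current_c + config.up_step, config.ceiling_c)
        s.step = target - state.current_c
        s.last_correct_c = state.current_c
        s.consecutive_incorrect = 0
        s.next_c = target
    elif state.consecutive_incorrect == 0:
        s.consecutive_incorrect = 1
        s.next_c = state.current_c  # repeat at the same complexity
    else:
        target = (state.last_correct_c + state.current_c) / 2.0
        s.step = target - state.current_c
        s.consecutive_incorrect = 0
        s.just_reverted = True
        s.next_c = target
    return s


def should_terminate(state: AdaptiveState, config: AdaptiveConfig) -> bool:
    """True once the staircase has converged or hit a boundary.

    Triggers on a correct answer at the ceiling, on a difficulty change
    smaller in magnitude than ``min_step``, or on the item cap.  The
    same-complexity repeat after a single miss is not a difficulty change
    and never triggers the step criterion.
    """
    if state.terminated or state.at_ceiling_correct:
        return True
    if state.step is not None and abs(state.step) < config.min_step:
        return True
    return state.n_items >= config.max_items


@dataclass
class SessionLog:
    """Complete record of one adaptive (or fixed-schedule) session."""

    game: str
    mode: str
    seed: int | None
    records: list[ItemRecord]
    final_c: float
    total_score: int
    config: dict = field(default_factory=dict)


ItemProvider = Callable[[float], tuple[object, cx.ComplexityBreakdown]]
Responder = Callable[[object, cx.ComplexityBreakdown], tuple[bool, float]]


def run_session(
    game: str,
    responder: Responder,
    adaptive_config: AdaptiveConfig,
    rng: np.random.Generator,
    *,
    generator_config: gen.GeneratorConfig | None = None,
    item_provider: ItemProvider | None = None,
    params: cx.ComplexityParams = cx.DEFAULT_PARAMS,
    seed: int | None = None,
) -> SessionLog:
    """Run a full adaptive session against a responder callable.

    ``responder(item, breakdown) -> (correct, completion_time)``.  Items
    come from ``item_provider(target_c)`` when given, otherwise from the
    game's generator with tolerance/dims from ``generator_config``.  The
    staircase state is updated on the *achieved* item complexity, not the
    requested target, since the generator only guarantees the tolerance.
    """
    if item_provider is None:
        if generator_config is None:
            generator_config = gen.GeneratorConfig(c_d=adaptive_config.start_c)

        def item_provider(target_c: float):
            cfg = replace(generator_config, c_d=target_c)
            return gen.generate_item(game, cfg, rng, params)

    state = initial_state(config=adaptive_config)
    records: list[ItemRecord] = []
    while not should_terminate(state, adaptive_config):
        target = state.next_c
        item, bd = item_provider(target)
        state = replace(
            state,
            current_c=bd.c_play,
            current_at_ceiling=target >= adaptive_config.ceiling_c - 1e-9,
        )
        correct, completion_time = responder(item, bd)
        context = scoring.AdaptiveScoreContext(
            repeated_same_complexity=(state.consecutive_incorrect == 1),
            after_two_misses=state.just_reverted,
        )
        outcome = scoring.outcome_for_item(game, item, correct, completion_time)
        score = scoring.score_adaptive(outcome, context)
        state = update(state, correct, adaptive_config)
        records.append(
            ItemRecord(
                index=len(records),
                target_c=target,
                c_play=bd.c_play,
                correct=correct,
                completion_time=completion_time,
                score=score,
                breakdown=bd.as_dict(),
            )
        )
    return SessionLog(
        game=game,
        mode="adaptive",
        seed=seed,
        records=records,
        final_c=state.next_c,
        total_score=sum(r.score for r in records),
        config={
            "start_c": adaptive_config.start_c,
            "ceiling_c": adaptive_config.ceiling_c,
            "up_step": adaptive_config.up_step,
            "min_step": adaptive_config.min_step,
            "max_items": adaptive_config.max_items,
        },
    )
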