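"""Serial reversal task: adaptive feedback controller and block scheduler.

The task presents two response options (left/right). In ``right_better``
blocks the right option is rewarded at ``target_rate`` (default 80%) and the
left at ``1 - target_rate``; ``left_better`` mirrors this; ``neutral`` blocks
pay both sides at ``neutral_rate`` (default 50%). Outcome rates are enforced
adaptively per block by a tally controller rather than by i.i.d. draws: a
side is rewarded whenever its within-block rewarded fraction has fallen below
its target. Blocks reverse after ``max_block_len`` trials, or once
``min_block_len`` trials are complete and the within-block correct fraction
has reached ``criterion``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SIDES = ("left", "right")
BLOCK_TYPES = ("right_better", "left_better", "neutral")

REWARD = "reward"
PUNISHMENT = "punishment"

#: reversal causes recorded on the final trial of a block
CAUSE_CRITERION = "criterion"
CAUSE_MAX_LENGTH = "max_length"
CAUSE_SESSION_END = "session_end"

EVENT_COLUMNS = [
    "subject_id", "session", "trial", "block_id", "block_type",
    "choice", "outcome", "valid", "correct", "reversal_cause",
]


class SchedulingError(RuntimeError):
    """Raised when feedback is requested for a closed block."""


@dataclass
class TaskConfig:
    """Configuration of the serial reversal task.

    Defaults follow the standard design: two sessions of 100 trials,
    80/20 contingencies, reversal after 16 trials or at >=70% correct
    once 10 trials are complete.
    """

    n_sessions: int = 2
    trials_per_session: int = 100
    target_rate: float = 0.8
    neutral_rate: float = 0.5
    max_block_len: int = 16
    min_block_len: int = 10
    criterion: float = 0.7
    block_type_sequence_policy: str = "cycle"
    block_type_cycle: tuple = ("right_better", "left_better")
    neutral_criterion_proxy: bool = False
    miss_prob: float = 0.0
    seed: int | None = None
    # timing metadata only -- no response-time model
    iti_jitter_s: tuple = (1.0, 6.5)
    response_deadline_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.criterion < 1.0:
            raise ValueError("criterion must lie in (0, 1)")
        if not self.min_block_len < self.max_block_len:
            raise ValueError("min_block_len must be < max_block_len")
        if not 0.5 < self.target_rate < 1.0:
            raise ValueError("target_rate must lie in (0.5, 1)")
        if not 0.0 < self.neutral_rate < 1.0:
            raise ValueError("neutral_rate must lie in (0, 1)")
        if self.block_type_sequence_policy not in ("cycle", "random"):
            raise ValueError("block_type_sequence_policy must be 'cycle' or 'random'")
        for bt in self.block_type_cycle:
            if bt not in BLOCK_TYPES:
                raise ValueError(f"unknown block type {bt!r}")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ValueError("miss_prob must lie in [0, 1)")


@dataclass
class BlockState:
    """Per-block tallies driving the adaptive controller and the scheduler."""

    block_type: str
    block_id: int = 0
    rewarded: dict = field(default_factory=lambda: {"left": 0, "right": 0})
    punished: dict = field(default_factory=lambda: {"left": 0, "right": 0})
    trials_elapsed: int = 0
    corrects_elapsed: int = 0
    closed: bool = False
    end_cause: str | None = None

    @property
    def better_side(self) -> str | None:
        if self.block_type == "right_better":
            return "right"
        if self.block_type == "left_better":
            return "left"
        return None

    def choices_of(self, side: str) -> int:
        return self.rewarded[side] + self.punished[side]


def _fraction(numerator: int, denominator: int) -> float:
    """Empty tallies count as rate 0, so any positive target is unmet."""
    return 0.0 if denominator == 0 else numerator / denominator


def deliver_feedback(state: BlockState, choice: str, config: TaskConfig) -> str:
    """Deliver reward or punishment for ``choice`` and update block tallies.

    Better side: reward iff the side's within-block rewarded fraction is
    strictly below ``target_rate``. Worse side: the mirrored rule --
    punishment iff the side's punished fraction is strictly below
    ``target_rate``. Neutral blocks: reward iff the rewarded fraction is
    below ``neutral_rate``. Fractions are computed before the current trial.
    """
    if state.closed:
        raise SchedulingError("feedback requested for a closed block")
    if choice not in SIDES:
        raise ValueError(f"invalid choice {choice!r}")

    n = state.choices_of(choice)
    if state.block_type == "neutral":
        outcome = REWARD if _fraction(state.rewarded[choice], n) < config.neutral_rate else PUNISHMENT
    elif choice == state.better_side:
        outcome = REWARD if _fraction(state.rewarded[choice], n) < config.target_rate else PUNISHMENT
    else:
        # mirrored punishment rule for the worse side
        outcome = PUNISHMENT if _fraction(state.punished[choice], n) < config.target_rate else REWARD

    if outcome == REWARD:
        state.rewarded[choice] += 1
    else:
        state.punished[choice] += 1
    state.trials_elapsed += 1
    if state.better_side is not None and choice == state.better_side:
        state.corrects_elapsed += 1
    return outcome


def schedule(state: BlockState, config: TaskConfig) -> str:
    """Decide at the end of a completed trial whether the block reverses.

    Returns ``"reverse"`` iff the block has run ``max_block_len`` trials, or
    has run at least ``min_block_len`` trials with a within-block correct
    fraction at or above ``criterion``. On reversal the block is closed and
    ``state.end_cause`` records which rule fired (criterion takes precedence
    when both hold on the same trial). Neutral blocks have no correct side
    and, unless ``neutral_criterion_proxy`` is set, only end at max length.
    """
    criterion_applies = state.better_side is not None or config.neutral_criterion_proxy
    if (
        criterion_applies
        and state.trials_elapsed >= config.min_block_len
        and _fraction(state.corrects_elapsed, state.trials_elapsed) >= config.criterion
    ):
        state.closed = True
        state.end_cause = CAUSE_CRITERION
        return "reverse"
    if state.trials_elapsed >= config.max_block_len:
        state.closed = True
        state.end_cause = CAUSE_MAX_LENGTH
        return "reverse"
    return "continue"


@dataclass
class TrialRecord:
    """One choice/outcome event with its block context."""

    subject_id: str
    session: int
    trial: int
    block_id: int
    block_type: str
    choice: str | None
    outcome: str | None
    valid: bool
    correct: bool
    reversal_cause: str | None = None


class Agent:
    """Base choice policy: per-trial left-choice probability plus learning hooks."""

    def reset(self) -> None:
        """Called at the start of each session."""

    def p_left(self, block_type: str) -> float:
        raise NotImplementedError

    def update(self, choice: str, outcome: str) -> None:
        """Called after feedback on valid trials."""

    def on_invalid(self) -> None:
        """Called instead of update on missed trials."""


class ConstantAgent(Agent):
    def __init__(self, side: str):
        if side not in SIDES:
            raise ValueError(f"invalid side {side!r}")
        self.side = side

    def p_left(self, block_type: str) -> float:
        return 1.0 if self.side == "left" else 0.0


class RandomAgent(Agent):
    def __init__(self, p_left: float = 0.5):
        self._p = p_left

    def p_left(self, block_type: str) -> float:
        return self._p


class BetterSideAgent(Agent):
    """Oracle agent that always picks the currently better side (right in neutral)."""

    def p_left(self, block_type: str) -> float:
        return 1.0 if block_type == "left_better" else 0.0


class WorseSideAgent(Agent):
    """Oracle agent that always picks the currently worse side (left in neutral)."""

    def p_left(self, block_type: str) -> float:
        return 0.0 if block_type == "left_better" else 1.0


def _next_block_type(index: int, config: TaskConfig, rng: np.random.Generator) -> str:
    if config.block_type_sequence_policy == "random":
        return str(rng.choice(config.block_type_cycle))
    return config.block_type_cycle[index % len(config.block_type_cycle)]


def simulate_session(
    agent: Agent,
    config: TaskConfig,
    seed: int | None = None,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Run ``agent`` through all sessions of the task; reproducible under seed.

    Returns exactly ``trials_per_session`` records per session. Missed trials
    (probability ``config.miss_prob``) carry no choice or outcome; they
    advance the block clock but contribute no correct-choice tally.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    block_id = 0
    block_index = 0  # position in the block-type sequence, runs across sessions

    for session in range(config.n_sessions):
        agent.reset()
        block: BlockState | None = None
        for trial in range(config.trials_per_session):
            if block is None or block.closed:
                if block is not None:
                    block_id += 1
                    block_index += 1
                block = BlockState(_next_block_type(block_index, config, rng), block_id)

            if config.miss_prob > 0.0 and rng.random() < config.miss_prob:
                block.trials_elapsed += 1
                agent.on_invalid()
                rec = TrialRecord(subject_id, session, trial, block.block_id,
                                  block.block_type, None, None, False, False)
            else:
                p = float(agent.p_left(block.block_type))
                if not 0.0 <= p <= 1.0 or not math.isfinite(p):
                    raise ValueError(f"agent returned invalid probability {p!r}")
                choice = "left" if rng.random() < p else "right"
                outcome = deliver_feedback(block, choice, config)
                agent.update(choice, outcome)
                correct = block.better_side is not None and choice == block.better_side
                rec = TrialRecord(subject_id, session, trial, block.block_id,
                                  block.block_type, choice, outcome, True, correct)

            if schedule(block, config) == "reverse":
                rec.reversal_cause = block.end_cause
            records.append(rec)

        if block is not None and not block.closed:
            records[-1].reversal_cause = CAUSE_SESSION_END
            block.closed = True
            block.end_cause = CAUSE_SESSION_END
        block_id += 1
        block_index += 1

    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    return df[EVENT_COLUMNS]


def simulate_session_frame(agent: Agent, config: TaskConfig, seed: int | None = None,
                           subject_id: str = "sim") -> pd.DataFrame:
    return records_to_frame(simulate_session(agent, config, seed, subject_id))
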