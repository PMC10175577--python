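"""Adaptive n-back task engine.

The n-back is a continuous-performance working-memory task: stimuli are
presented one at a time and the participant presses a key whenever the
current stimulus matches the one shown *n* positions earlier, where *n* is
the load level.  A training session consists of eight blocks.  Each block
has ``20 + n`` screens: the first *n* screens are lead-in (a match is not
yet defined there) and the remaining 20 are *critical* screens, six of
which are targets.  Accuracy on the critical screens drives a one-up /
one-down staircase: >=90% raises the load of the next block by one, <=70%
lowers it by one (never below 1), anything in between leaves it unchanged.
The session outcome is the mean load level of the last five blocks.

The engine is turn-based: stimulus/ISI durations are carried as metadata
only and no wall-clock behaviour is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "VERBAL_ALPHABET",
    "TaskConfig",
    "Block",
    "BlockResult",
    "SessionRecord",
    "BlockConstraintError",
    "generate_block",
    "score_block",
    "staircase_update",
    "run_session",
    "LogisticResponder",
    "omniscient_responder",
    "mute_responder",
]

#: The eight lowercase consonants used as verbal stimuli.
VERBAL_ALPHABET = ("c", "g", "h", "k", "p", "q", "t", "w")


class BlockConstraintError(ValueError):
    """Raised when a block cannot be built under the stated constraints."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one n-back task variant.

    Defaults reproduce the verbal task: 8 consonant stimuli, 8 blocks of
    20 critical screens with 6 targets, 90%/70% staircase thresholds, two
    1-back blocks then a 2-back block before the staircase takes over, and
    the outcome averaged over the last 5 blocks.  The spatial variant only
    differs in the stimulus alphabet (9 grid cells).
    """

    modality: str = "verbal"
    alphabet_size: int = 8
    n_blocks: int = 8
    critical_screens: int = 20
    targets_per_block: int = 6
    acc_up: float = 0.90
    acc_down: float = 0.70
    min_level: int = 1
    max_level: int = 12  # runtime bound only; the task itself has no ceiling
    start_levels: tuple[int, ...] = (1, 1, 2)
    outcome_window: int = 5
    stim_ms: int = 1000  # metadata only
    isi_ms: int = 2000  # metadata only

    def __post_init__(self) -> None:
        if not self.acc_down < self.acc_up:
            raise ValueError("acc_down must be below acc_up")
        if self.targets_per_block > self.critical_screens:
            raise ValueError("more targets than critical screens")
        if self.outcome_window > self.n_blocks:
            raise ValueError("outcome window longer than the session")

    @classmethod
    def verbal(cls, **kw) -> "TaskConfig":
        return cls(modality="verbal", alphabet_size=len(VERBAL_ALPHABET), **kw)

    @classmethod
    def spatial(cls, **kw) -> "TaskConfig":
        # 3 x 3 grid: nine cells, one illuminated per screen
        return cls(modality="spatial", alphabet_size=9, **kw)


@dataclass(frozen=True)
class Block:
    """One generated n-back block.

    ``stimuli`` holds integer stimulus identifiers (an index into the
    alphabet); ``is_target`` flags the screens whose stimulus repeats the
    one ``level`` steps back.  Length is ``critical_screens + level`` and
    the first ``level`` screens are never targets.
    """

    level: int
    stimuli: tuple[int, ...]
    is_target: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.stimuli)

    def to_json(self) -> str:
        return json.dumps(
            {"level": self.level, "stimuli": list(self.stimuli),
             "is_target": [bool(t) for t in self.is_target]}
        )

    @classmethod
    def from_json(cls, s: str) -> "Block":
        d = json.loads(s)
        return cls(level=d["level"], stimuli=tuple(d["stimuli"]),
                   is_target=tuple(bool(t) for t in d["is_target"]))


@dataclass(frozen=True)
class BlockResult:
    responses: tuple[bool, ...]
    accuracy: float


@dataclass(frozen=True)
class SessionRecord:
    """Eight block levels and accuracies plus the session outcome.

    ``outcome`` is the mean load level of the last ``outcome_window``
    blocks (by default blocks 4-8).
    """

    levels: tuple[int, ...]
    accuracies: tuple[float, ...]
    outcome: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SessionRecord":
        d = json.loads(s)
        return cls(levels=tuple(d["levels"]),
                   accuracies=tuple(d["accuracies"]), outcome=d["outcome"])


def generate_block(level: int, config: TaskConfig,
                   rng: np.random.Generator) -> Block:
    """Generate one pseudo-randomised block at the given load level.

    Target positions are drawn uniformly without replacement from the
    ``critical_screens`` critical slots and re-drawn for every block.
    Stimuli are laid down left to right: a target copies the stimulus
    ``level`` steps back, a non-target critical screen samples uniformly
    from the alphabet excluding that single stimulus (lures at other lags
    are permitted), and the lead-in screens sample the full alphabet.
    """
    if level < config.min_level:
        raise ValueError(f"level must be >= {config.min_level}, got {level}")
    if config.alphabet_size < 2:
        raise BlockConstraintError(
            "alphabet_size must be >= 2 so a non-target can differ from "
            "the stimulus n back")

    n_screens = config.critical_screens + level
    critical = np.arange(level, n_screens)
    target_pos = rng.choice(critical, size=config.targets_per_block,
                            replace=False)
    is_target = np.zeros(n_screens, dtype=bool)
    is_target[target_pos] = True

    stimuli = np.empty(n_screens, dtype=np.int64)
    lead = rng.integers(0, config.alphabet_size, size=level)
    stimuli[:level] = lead
    for i in range(level, n_screens):
        anchor = stimuli[i - level]
        if is_target[i]:
            stimuli[i] = anchor
        else:
            # draw from alphabet \ {anchor} without rejection
            draw = rng.integers(0, config.alphabet_size - 1)
            stimuli[i] = draw if draw < anchor else draw + 1
    return Block(level=level, stimuli=tuple(int(s) for s in stimuli),
                 is_target=tuple(bool(t) for t in is_target))


def score_block(block: Block, responses: Sequence[bool]) -> BlockResult:
    """Score one block: accuracy over the last 20 (critical) screens.

    A hit is a response at a target, a correct rejection is no response at
    a non-target; accuracy = (hits + correct rejections) / 20.  Responses
    during the lead-in screens do not enter the score.
    """
    responses = tuple(bool(r) for r in responses)
    if len(responses) != len(block):
        raise ValueError(
            f"responses length {len(responses)} != block length {len(block)}")
    n_crit = len(block) - block.level
    resp = np.asarray(responses[block.level:], dtype=bool)
    targ = np.asarray(block.is_target[block.level:], dtype=bool)
    correct = int(np.sum(resp == targ))
    return BlockResult(responses=responses, accuracy=correct / n_crit)


def staircase_update(level: int, accuracy: float, config: TaskConfig) -> int:
    """One-step staircase rule: up at >=90%, down at <=70%, else hold."""
    if level < config.min_level:
        raise ValueError("level below minimum")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy outside [0, 1]")
    if accuracy >= config.acc_up:
        return min(level + 1, config.max_level)
    if accuracy <= config.acc_down:
        return max(level - 1, config.min_level)
    return level


Responder = Callable[[Block, np.random.Generator], Sequence[bool]]


def run_session(responder: Responder, config: TaskConfig,
                rng: np.random.Generator) -> SessionRecord:
    """Run one eight-block session under the adaptive staircase.

    Blocks 1-2 run at level 1 and block 3 at level 2; from block 4 onward
    each block's level is the staircase update of the previous block's
    level and accuracy.  The outcome is the mean level of the last
    ``outcome_window`` blocks.
    """
    levels: list[int] = []
    accs: list[float] = []
    level = config.start_levels[0]
    for k in range(config.n_blocks):
        if k < len(config.start_levels):
            level = config.start_levels[k]
        else:
            level = staircase_update(levels[-1], accs[-1], config)
        block = generate_block(level, config, rng)
        responses = responder(block, rng)
        responses = tuple(bool(r) for r in responses)
        if len(responses) != len(block):
            raise ValueError("responder returned a malformed sequence")
        result = score_block(block, responses)
        levels.append(level)
        accs.append(result.accuracy)
    outcome = float(np.mean(levels[-config.outcome_window:]))
    return SessionRecord(levels=tuple(levels), accuracies=tuple(accs),
                         outcome=outcome)


@dataclass(frozen=True)
class LogisticResponder:
    """Stochastic responder with a latent working-memory capacity.

    At load level L the probability of performing the *correct action* on
    any one screen (press at a target, withhold at a non-target) is

        p = lapse/2 + (1 - lapse) * logistic(discrim * (capacity - L))

    so performance degrades smoothly as the load exceeds capacity, with a
    floor/ceiling set by the lapse rate.  ``discrim`` is the logistic
    steepness per load-level unit.
    """

    capacity: float
    discrim: float = 3.0
    lapse: float = 0.05

    def p_correct(self, level: int) -> float:
        return float(self.lapse / 2.0
                     + (1.0 - self.lapse)
                     * expit(self.discrim * (self.capacity - level)))

    def __call__(self, block: Block,
                 rng: np.random.Generator) -> tuple[bool, ...]:
        p = self.p_correct(block.level)
        correct_act = rng.random(len(block)) < p
        targ = np.asarray(block.is_target, dtype=bool)
        # correct action means press at targets, withhold elsewhere
        responses = np.where(targ, correct_act, ~correct_act)
        return tuple(bool(r) for r in responses)


def omniscient_responder(block: Block,
                         rng: np.random.Generator) -> tuple[bool, ...]:
    """Perfect performance: respond exactly at the targets."""
    return tuple(block.is_target)


def mute_responder(block: Block,
                   rng: np.random.Generator) -> tuple[bool, ...]:
    """Never responds; accuracy is the correct-rejection rate 14/20."""
    return tuple(False for _ in range(len(block)))
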