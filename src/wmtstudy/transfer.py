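"""Scoring and simulation of the transfer tasks.

Near transfer: forward and backward digit span.  Two trials are given at
each string length (forward 3-9, backward 2-8); the length increases after
at least one correct trial and the task stops after two failures at the
same length.  The span is the longest administered length with at least
one correct trial.  Failing both trials at the very first length scores
one below the protocol minimum (forward 2, backward 1), which keeps the
scale ordinal while staying distinguishable from missing data.

Far transfer: a timed relational-reasoning test (matrix puzzles of
increasing difficulty); the score is the number of puzzles solved within
the 5-minute limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SpanProtocol",
    "SpanTrial",
    "SpanOutcome",
    "DSF_PROTOCOL",
    "DSB_PROTOCOL",
    "ProtocolViolationError",
    "judge_span_trial",
    "score_digit_span",
    "score_reasoning",
    "simulate_digit_span",
    "simulate_reasoning",
]


class ProtocolViolationError(ValueError):
    """Trials continue past the stop rule or otherwise break the protocol."""


@dataclass(frozen=True)
class SpanProtocol:
    direction: str  # "forward" | "backward"
    min_length: int
    max_length: int
    trials_per_length: int = 2

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.min_length > self.max_length:
            raise ValueError("empty length range")

    @property
    def lengths(self) -> range:
        return range(self.min_length, self.max_length + 1)

    @property
    def floor_span(self) -> int:
        return self.min_length - 1


DSF_PROTOCOL = SpanProtocol("forward", 3, 9)
DSB_PROTOCOL = SpanProtocol("backward", 2, 8)


@dataclass(frozen=True)
class SpanTrial:
    length: int
    correct: bool


@dataclass(frozen=True)
class SpanOutcome:
    trials: tuple[SpanTrial, ...]
    span: int


def judge_span_trial(presented, typed: str, direction: str) -> bool:
    """Judge one digit-span trial.

    ``presented`` is the digit sequence shown; ``typed`` the participant's
    typed answer, whitespace-stripped before comparison.  Forward recall
    must reproduce the sequence verbatim, backward recall in reverse.  Any
    length mismatch, digit difference, or non-digit character scores
    false (never raises).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    typed = "".join(typed.split())
    if not typed.isdigit():
        return False
    expected = "".join(str(int(d)) for d in presented)
    if direction == "backward":
        expected = expected[::-1]
    return typed == expected


def score_digit_span(trials: list[SpanTrial] | tuple[SpanTrial, ...],
                     protocol: SpanProtocol) -> int:
    """Score an administered digit-span run.

    ``trials`` are in administration order: ``trials_per_length`` trials
    per length, lengths ascending from the protocol minimum, stopping
    after the first length with every trial incorrect.  The span is the
    maximum length with at least one correct trial, or
    ``protocol.floor_span`` when no length passed.
    """
    k = protocol.trials_per_length
    if len(trials) % k != 0:
        raise ProtocolViolationError("partial trial set at some length")
    span = protocol.floor_span
    expected_len = protocol.min_length
    stopped = False
    for i in range(0, len(trials), k):
        if stopped:
            raise ProtocolViolationError(
                "trials continue past a double failure")
        chunk = trials[i:i + k]
        if any(t.length != expected_len for t in chunk):
            raise ProtocolViolationError(
                f"expected trials at length {expected_len}")
        if expected_len > protocol.max_length:
            raise ProtocolViolationError("trials beyond protocol maximum")
        n_correct = sum(t.correct for t in chunk)
        if n_correct >= 1:
            span = expected_len
            expected_len += 1
            if span == protocol.max_length:
                stopped = True  # range exhausted; ceiling
        else:
            stopped = True
    return span


def score_reasoning(responses: list[tuple[bool, float]],
                    limit: float = 300.0) -> int:
    """Count correct reasoning solutions completed within the time limit.

    ``responses`` is a list of (correct, elapsed-seconds) pairs with
    non-decreasing elapsed times; answers finishing after ``limit`` are
    excluded.
    """
    last = 0.0
    count = 0
    for correct, elapsed in responses:
        if elapsed < 0:
            raise ValueError("negative elapsed time")
        if elapsed < last:
            raise ValueError("elapsed times must be non-decreasing")
        last = elapsed
        if elapsed <= limit and correct:
            count += 1
    return count


def simulate_digit_span(latent_span: float, protocol: SpanProtocol,
                        rng: np.random.Generator,
                        noise_sd: float = 0.0) -> SpanOutcome:
    """Simulate one digit-span administration for a latent span.

    Per-trial success probability is 1 when the string length is at most
    the latent span and 0 beyond it (``noise_sd = 0``), or the logistic
    smoothing ``logistic((latent - length) / noise_sd)`` otherwise.  The
    administration obeys the increase/stop rules and is scored with
    :func:`score_digit_span`.
    """
    trials: list[SpanTrial] = []
    for length in protocol.lengths:
        if noise_sd <= 0:
            p = 1.0 if length <= latent_span else 0.0
        else:
            p = float(expit((latent_span - length) / noise_sd))
        chunk = [SpanTrial(length, bool(rng.random() < p))
                 for _ in range(protocol.trials_per_length)]
        trials.extend(chunk)
        if not any(t.correct for t in chunk):
            break
    return SpanOutcome(trials=tuple(trials),
                       span=score_digit_span(trials, protocol))


def simulate_reasoning(ability: float, rng: np.random.Generator,
                       n_items: int = 30, limit: float = 300.0,
                       discrim: float = 1.2,
                       mean_item_s: float = 18.0) -> int:
    """Simulate a timed reasoning run for a latent ability (z-score scale).

    Items get harder as the test proceeds: item i has success probability
    logistic(discrim * (ability - (i - 12)/5)), and takes
    ``8 + Exponential(mean_item_s - 8)`` seconds, so a typical run answers
    roughly 15 items within the 5-minute limit.
    """
    t = 0.0
    responses: list[tuple[bool, float]] = []
    for i in range(1, n_items + 1):
        t += 8.0 + rng.exponential(mean_item_s - 8.0)
        if t > limit:
            break
        difficulty = (i - 12.0) / 5.0
        p = float(expit(discrim * (ability - difficulty)))
        responses.append((bool(rng.random() < p), t))
    return score_reasoning(responses, limit=limit)
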