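"""Adaptive delay-discounting titration task.

The task presents repeated choices between a present monetary amount and a
fixed future amount (default US$1,000) delivered after one of seven delay
periods.  Within each delay series the present offer starts at half the
future amount and is adjusted after every choice by a halving rule: the
change on the upcoming trial ``t`` (2-based within the series) is
``initial_present / 2**(t - 1)``, subtracted after a "present" choice and
added after a "future" choice.  Six titration trials per delay implement a
six-step bisection of the interval (0, future_amount), so every offer is an
exact dyadic rational (a multiple of ``initial_present / 2**trials_per_delay``)
and is representable exactly in binary floating point — the staircase is
bit-reproducible.

Catch trials with one strictly dominating option are interleaved at fixed
positions to detect inattentive responding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

from .errors import (
    ConfigError,
    CorruptedSessionError,
    InvalidStepError,
    ProtocolError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .agents import Agent

#: Delay periods in days: two weeks, one month, six months, one year,
#: three years, five years, ten years (month = 30 d, year = 365 d).
DEFAULT_DELAYS: tuple[float, ...] = (14.0, 30.0, 182.0, 365.0, 1095.0, 1825.0, 3650.0)

TITRATION_CHOICES = ("present", "future")
CATCH_CHOICES = ("a", "b")


@dataclass(frozen=True)
class CatchSpec:
    """An attention-check choice in which one option strictly dominates.

    Each option is an ``(amount, delay_days)`` pair.  The dominating option
    offers at least as much money at no longer a delay, with at least one of
    the two comparisons strict; ``correct`` names it (``"a"`` or ``"b"``).
    """

    option_a: tuple[float, float]
    option_b: tuple[float, float]
    correct: str

    def __post_init__(self) -> None:
        if self.correct not in CATCH_CHOICES:
            raise ConfigError(f"catch 'correct' must be 'a' or 'b', got {self.correct!r}")
        (aa, da), (ab, db) = self.option_a, self.option_b
        win, lose = ((aa, da), (ab, db)) if self.correct == "a" else ((ab, db), (aa, da))
        dominates = win[0] >= lose[0] and win[1] <= lose[1] and (
            win[0] > lose[0] or win[1] < lose[1]
        )
        if not dominates:
            raise ConfigError(
                f"catch option {self.correct!r} does not strictly dominate: "
                f"a={self.option_a}, b={self.option_b}"
            )


DEFAULT_CATCH_TRIALS: tuple[CatchSpec, ...] = (
    CatchSpec(option_a=(1000.0, 0.0), option_b=(500.0, 1825.0), correct="a"),
    CatchSpec(option_a=(1000.0, 14.0), option_b=(500.0, 3650.0), correct="a"),
    CatchSpec(option_a=(500.0, 365.0), option_b=(1000.0, 0.0), correct="b"),
    CatchSpec(option_a=(250.0, 1095.0), option_b=(1000.0, 30.0), correct="b"),
)

#: 0-based indices of the catch trials in the 46-trial order.
DEFAULT_CATCH_POSITIONS: tuple[int, ...] = (12, 23, 34, 45)


@dataclass(frozen=True)
class TaskConfig:
    """The titration design: delays, trial counts, anchors, catch trials.

    Defaults reproduce the deployed task: seven delay periods, six titration
    trials each, four catch trials — 46 trials in total — with the future
    option fixed at $1,000 and the first present offer at $500.
    """

    future_amount: float = 1000.0
    initial_present: float = 500.0
    delays: tuple[float, ...] = DEFAULT_DELAYS
    trials_per_delay: int = 6
    catch_trials: tuple[CatchSpec, ...] = DEFAULT_CATCH_TRIALS
    catch_positions: tuple[int, ...] = DEFAULT_CATCH_POSITIONS

    def __post_init__(self) -> None:
        if not (self.future_amount > self.initial_present > 0):
            raise ConfigError("need future_amount > initial_present > 0")
        if len(self.delays) == 0 or any(d <= 0 for d in self.delays):
            raise ConfigError("delays must be non-empty and positive")
        if any(b <= a for a, b in zip(self.delays, self.delays[1:])):
            raise ConfigError("delays must be strictly increasing")
        if self.trials_per_delay < 1:
            raise ConfigError("trials_per_delay must be >= 1")
        if len(self.catch_positions) != len(self.catch_trials):
            raise ConfigError("catch_positions must match catch_trials in length")
        if len(set(self.catch_positions)) != len(self.catch_positions):
            raise ConfigError("catch_positions overlap")
        n = self.n_trials
        if any(not (0 <= p < n) for p in self.catch_positions):
            raise ConfigError(f"catch_positions must lie in [0, {n})")

    @property
    def n_trials(self) -> int:
        """Total trial count: len(delays)*trials_per_delay + len(catch_trials)."""
        return len(self.delays) * self.trials_per_delay + len(self.catch_trials)

    def to_dict(self) -> dict:
        return {
            "future_amount": self.future_amount,
            "initial_present": self.initial_present,
            "delays": list(self.delays),
            "trials_per_delay": self.trials_per_delay,
            "catch_trials": [
                {"option_a": list(c.option_a), "option_b": list(c.option_b), "correct": c.correct}
                for c in self.catch_trials
            ],
            "catch_positions": list(self.catch_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "delays" in d:
            d["delays"] = tuple(float(x) for x in d["delays"])
        if "catch_trials" in d:
            d["catch_trials"] = tuple(
                CatchSpec(tuple(c["option_a"]), tuple(c["option_b"]), c["correct"])
                for c in d["catch_trials"]
            )
        if "catch_positions" in d:
            d["catch_positions"] = tuple(int(p) for p in d["catch_positions"])
        return cls(**d)

    def fingerprint(self) -> str:
        """Short stable hash of the design, embedded in every output artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class Trial:
    """One presented choice.

    Titration trials carry a delay and a present/future offer pair
    (``present_offer`` is ``None`` in a schedule and resolved at run time);
    catch trials carry their :class:`CatchSpec` instead.
    ``within_delay_index`` is the 1-based titration step within the series.
    """

    global_index: int
    is_catch: bool
    delay_days: Optional[float] = None
    present_offer: Optional[float] = None
    future_offer: Optional[float] = None
    within_delay_index: Optional[int] = None
    catch: Optional[CatchSpec] = None


@dataclass(frozen=True)
class SessionRecord:
    """One participant's completed session: ordered (Trial, choice) pairs."""

    participant_id: str
    trials: tuple[tuple[Trial, str], ...]
    seed: int
    config_fingerprint: str


def update_present_offer(
    current_offer: float,
    choice: str,
    next_within_delay_index: int,
    config: TaskConfig,
) -> float:
    """Titrate the present offer for the upcoming trial of a delay series.

    The change amount is ``initial_present / 2**(next_within_delay_index - 1)``;
    it is subtracted if the just-made ``choice`` was "present" and added if it
    was "future".  With the default design the successive changes are
    250, 125, 62.5, 31.25, 15.625.
    """
    if choice not in TITRATION_CHOICES:
        raise ProtocolError(f"invalid titration choice token {choice!r}")
    if not (2 <= next_within_delay_index <= config.trials_per_delay + 1):
        raise InvalidStepError(
            f"next_within_delay_index {next_within_delay_index} outside "
            f"[2, {config.trials_per_delay + 1}]"
        )
    if not (0 < current_offer < config.future_amount):
        raise CorruptedSessionError(
            f"present offer {current_offer} outside (0, {config.future_amount})"
        )
    change = config.initial_present / 2 ** (next_within_delay_index - 1)
    out = current_offer - change if choice == "present" else current_offer + change
    if not (0 < out < config.future_amount):
        raise CorruptedSessionError(
            f"titrated offer {out} escaped (0, {config.future_amount})"
        )
    return out


def build_schedule(config: TaskConfig) -> list[Trial]:
    """Deterministic trial order for a session.

    Delay series run in increasing-delay order with their titration trials
    contiguous among the non-catch slots; catch trials occupy
    ``config.catch_positions``.  Present offers are left unresolved (``None``)
    — they depend on the responder and are filled in by :func:`run_session`.
    """
    n = config.n_trials
    catch_at = dict(zip(config.catch_positions, config.catch_trials))
    schedule: list[Trial] = []
    series = [
        (d, w)
        for d in config.delays
        for w in range(1, config.trials_per_delay + 1)
    ]
    it = iter(series)
    for g in range(n):
        if g in catch_at:
            schedule.append(Trial(global_index=g, is_catch=True, catch=catch_at[g]))
        else:
            d, w = next(it)
            schedule.append(
                Trial(
                    global_index=g,
                    is_catch=False,
                    delay_days=d,
                    future_offer=config.future_amount,
                    within_delay_index=w,
                )
            )
    return schedule


def run_session(
    agent: "Agent",
    config: TaskConfig,
    seed: int,
    participant_id: str = "sim",
) -> SessionRecord:
    """Run one full session of the adaptive task against a simulated responder.

    Titration state is kept independently per delay series; each series
    starts at ``initial_present``.  All randomness (catch errors, stochastic
    choice) comes from one ``numpy`` generator seeded with ``seed``, so an
    identical (agent, config, seed) triple reproduces the record exactly.
    """
    rng = np.random.default_rng(seed)
    offers: dict[float, float] = {d: config.initial_present for d in config.delays}
    done: list[tuple[Trial, str]] = []
    for trial in build_schedule(config):
        if trial.is_catch:
            choice = agent.choose(trial, rng)
            if choice not in CATCH_CHOICES:
                raise ProtocolError(f"invalid catch choice token {choice!r}")
        else:
            d = trial.delay_days
            trial = replace(trial, present_offer=offers[d])
            choice = agent.choose(trial, rng)
            if choice not in TITRATION_CHOICES:
                raise ProtocolError(f"invalid titration choice token {choice!r}")
            if trial.within_delay_index < config.trials_per_delay:
                offers[d] = update_present_offer(
                    offers[d], choice, trial.within_delay_index + 1, config
                )
        done.append((trial, choice))
    return SessionRecord(
        participant_id=participant_id,
        trials=tuple(done),
        seed=int(seed),
        config_fingerprint=config.fingerprint(),
    )
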