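"""Scoring: indifference points, per-delay rates, k, (ln)k, validity.

A completed delay series of choices determines an indifference point — the
present offer that would have been shown on a hypothetical next trial,
equivalently the midpoint of the final bisection bracket:

    ip = initial_present + sum_{t=1..T} s_t * initial_present / 2**t

with s_t = +1 for a "future" choice on trial t and -1 for "present".
Inverting the hyperbolic value function at the indifference point gives the
per-delay discount rate k_d = (future_amount/ip - 1) / delay_days (per day).
The participant's k is the arithmetic mean of the per-delay k_d across the
seven series, and (ln)k = ln(k) — average first, log second.  Sessions with
catch-trial accuracy <= 50% are flagged invalid and excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import MalformedSessionError
from .task import SessionRecord, TaskConfig


class DelayEstimate(NamedTuple):
    delay_days: float
    indifference_point: float
    k_d: float


@dataclass(frozen=True)
class IndifferenceProfile:
    """Per-delay indifference points and discount rates for one session."""

    estimates: tuple[DelayEstimate, ...]


@dataclass(frozen=True)
class DiscountScore:
    """The session-level outcome: k, (ln)k and the catch-trial validity flag."""

    participant_id: str
    k: float
    ln_k: float
    catch_correct: int
    catch_total: int
    valid: bool
    profile: IndifferenceProfile


def indifference_point(choices: Sequence[str], config: TaskConfig) -> float:
    """Post-series indifference estimate from one delay's ordered choices.

    Returns the offer of a hypothetical trial ``trials_per_delay + 1`` (one
    more halving step), which is the midpoint of the final bracketing
    interval.  Always strictly inside (0, future_amount), so k and ln(k)
    are defined for every choice sequence.
    """
    if len(choices) != config.trials_per_delay:
        raise MalformedSessionError(
            f"expected {config.trials_per_delay} choices, got {len(choices)}"
        )
    ip = config.initial_present
    for t, c in enumerate(choices, start=1):
        if c not in ("present", "future"):
            raise MalformedSessionError(f"invalid choice token {c!r} at step {t}")
        sign = 1.0 if c == "future" else -1.0
        ip += sign * config.initial_present / 2**t
    return ip


def k_from_indifference(
    indifference_point: float, delay_days: float, future_amount: float
) -> float:
    """Hyperbolic inversion: k_d = (future_amount/ip - 1) / delay_days."""
    if not (0 < indifference_point < future_amount):
        raise ValueError(
            f"indifference point {indifference_point} outside (0, {future_amount})"
        )
    if delay_days <= 0:
        raise ValueError("delay_days must be positive")
    return (future_amount / indifference_point - 1.0) / delay_days


def score_choice_series(
    series: dict[float, Sequence[str]],
    config: TaskConfig,
    catch_correct: int,
    catch_total: int,
    participant_id: str = "sim",
) -> DiscountScore:
    """Score ordered per-delay choice sequences plus catch-trial counts."""
    if set(series) != set(config.delays):
        raise MalformedSessionError(
            f"delays {sorted(series)} do not match config delays {list(config.delays)}"
        )
    estimates = []
    for d in config.delays:
        ip = indifference_point(series[d], config)
        estimates.append(DelayEstimate(d, ip, k_from_indifference(ip, d, config.future_amount)))
    k = sum(e.k_d for e in estimates) / len(estimates)
    valid = True
    if catch_total > 0 and catch_correct / catch_total <= 0.5:
        valid = False
    return DiscountScore(
        participant_id=participant_id,
        k=k,
        ln_k=math.log(k),
        catch_correct=catch_correct,
        catch_total=catch_total,
        valid=valid,
        profile=IndifferenceProfile(tuple(estimates)),
    )


def score_session(session: SessionRecord, config: TaskConfig) -> DiscountScore:
    """Convert a completed SessionRecord into a DiscountScore."""
    if len(session.trials) != config.n_trials:
        raise MalformedSessionError(
            f"session has {len(session.trials)} trials, config expects {config.n_trials}"
        )
    series: dict[float, list[str]] = {d: [] for d in config.delays}
    catch_correct = 0
    catch_total = 0
    for trial, choice in session.trials:
        if trial.is_catch:
            catch_total += 1
            catch_correct += int(choice == trial.catch.correct)
        else:
            series[trial.delay_days].append(choice)
    for d, ch in series.items():
        if len(ch) != config.trials_per_delay:
            raise MalformedSessionError(
                f"delay {d}: {len(ch)} choices, expected {config.trials_per_delay}"
            )
    return score_choice_series(
        series, config, catch_correct, catch_total, session.participant_id
    )


def apply_exclusions(
    scores: Sequence[DiscountScore],
) -> tuple[list[DiscountScore], list[DiscountScore]]:
    """Partition scores into (retained, excluded) by the catch-accuracy rule,
    preserving order."""
    retained = [s for s in scores if s.valid]
    excluded = [s for s in scores if not s.valid]
    return retained, excluded
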