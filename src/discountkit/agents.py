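"""Simulated responders for the titration task.

All agents value delayed money with the hyperbolic discount function
``V = A / (1 + k*D)`` (amount A, delay D in days, discount rate k per day).
The deployed task's own scoring convention does not state a functional form;
hyperbolic discounting is the standard model for this task family and is
assumed throughout — see docs/methods.md.

Agents provide ground truth for parameter recovery: a deterministic
hyperbolic agent always picks the higher-valued option, a logistic agent
adds softmax choice noise, and an inattentive agent responds at random.
Catch trials are answered correctly with probability ``1 - catch_error_rate``
for every kind.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
from scipy.special import expit

from .errors import ConfigError
from .task import CATCH_CHOICES, Trial


def hyperbolic_value(amount: float, k: float, delay: float) -> float:
    """Subjective present value ``amount / (1 + k*delay)``.

    Equals ``amount`` when k = 0 or delay = 0 and is strictly decreasing in
    both k and delay for positive amounts.
    """
    if amount < 0 or k < 0 or delay < 0:
        raise ValueError("amount, k and delay must all be non-negative")
    return amount / (1.0 + k * delay)


class Agent(ABC):
    """Choice contract: map a presented Trial to a choice token.

    Titration trials yield "present"/"future"; catch trials yield "a"/"b".
    """

    def __init__(self, catch_error_rate: float = 0.0):
        if not (0.0 <= catch_error_rate <= 1.0):
            raise ConfigError("catch_error_rate must lie in [0, 1]")
        self.catch_error_rate = float(catch_error_rate)

    def choose(self, trial: Trial, rng: np.random.Generator) -> str:
        if trial.is_catch:
            return self._choose_catch(trial, rng)
        return self._choose_titration(trial, rng)

    def _choose_catch(self, trial: Trial, rng: np.random.Generator) -> str:
        correct = trial.catch.correct
        if rng.random() < self.catch_error_rate:
            return CATCH_CHOICES[1 - CATCH_CHOICES.index(correct)]
        return correct

    @abstractmethod
    def _choose_titration(self, trial: Trial, rng: np.random.Generator) -> str:
        ...  # pragma: no cover


class DeterministicHyperbolicAgent(Agent):
    """Always picks the option with the higher hyperbolic value.

    Exact ties are broken toward the future option (a fixed convention;
    ties can only occur on the dyadic offer grid).
    """

    def __init__(self, k_true: float, catch_error_rate: float = 0.0):
        super().__init__(catch_error_rate)
        if k_true < 0:
            raise ConfigError("k_true must be non-negative")
        self.k_true = float(k_true)

    def _choose_titration(self, trial: Trial, rng: np.random.Generator) -> str:
        v_future = hyperbolic_value(trial.future_offer, self.k_true, trial.delay_days)
        return "future" if v_future >= trial.present_offer else "present"


class LogisticHyperbolicAgent(Agent):
    """Softmax responder: P(future) = logistic(beta * (V_future - V_present)).

    ``inverse_temperature`` (beta, per dollar of value difference) scales
    choice noise; beta = 0 gives coin-flip responding and beta -> inf
    recovers the deterministic agent.
    """

    def __init__(
        self,
        k_true: float,
        inverse_temperature: float,
        catch_error_rate: float = 0.0,
    ):
        super().__init__(catch_error_rate)
        if k_true < 0:
            raise ConfigError("k_true must be non-negative")
        if inverse_temperature < 0:
            raise ConfigError("inverse_temperature must be non-negative")
        self.k_true = float(k_true)
        self.inverse_temperature = float(inverse_temperature)

    def _choose_titration(self, trial: Trial, rng: np.random.Generator) -> str:
        v_future = hyperbolic_value(trial.future_offer, self.k_true, trial.delay_days)
        p_future = expit(self.inverse_temperature * (v_future - trial.present_offer))
        return "future" if rng.random() < p_future else "present"


class InattentiveAgent(Agent):
    """Responds uniformly at random on titration trials."""

    def __init__(self, catch_error_rate: float = 0.5):
        super().__init__(catch_error_rate)

    def _choose_titration(self, trial: Trial, rng: np.random.Generator) -> str:
        return "future" if rng.random() < 0.5 else "present"


def make_agent(kind: str, **kwargs) -> Agent:
    """Build an agent from a simulation-config spec.

    ``kind`` is one of "deterministic_hyperbolic", "logistic_hyperbolic",
    "inattentive"; remaining keyword arguments are the kind's parameters.
    """
    kinds = {
        "deterministic_hyperbolic": DeterministicHyperbolicAgent,
        "logistic_hyperbolic": LogisticHyperbolicAgent,
        "inattentive": InattentiveAgent,
    }
    try:
        cls = kinds[kind]
    except KeyError:
        raise ConfigError(f"unknown agent kind {kind!r}; expected one of {sorted(kinds)}")
    return cls(**kwargs)
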