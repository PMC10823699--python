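"""Synthetic cohorts with the statistical structure of the study sample.

Three groups — ARFID (avoidant/restrictive food intake disorder), AN
(anorexia nervosa, restricting subtype) and HC (healthy controls) — at
n = 57/28/19.  Per group, (ln)k is sampled Normal(mean, SD) with the
published group summaries as defaults (−6.1 [2.0] / −7.3 [1.7] / −5.4 [1.5])
and age is sampled from a truncated normal on [10, 30] years
(17.42 [5.38] / 20.75 [3.76] / 21.32 [7.60]).  ARFID participants carry
three binary presentation flags (sensory sensitivity, fear of aversive
consequences, lack of interest in eating or food) whose realized column
sums equal the published marginals 45/18/24 exactly, with co-occurrence
allowed and every participant carrying at least one flag.

Two generation modes:

* ``direct`` — the sampled (ln)k is the outcome; no task simulation.
* ``behavioral`` — k_true = exp(sampled ln_k) parameterises an agent that
  actually plays the titration task; the outcome is the staircase-scored
  (ln)k, including catch-trial exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .agents import DeterministicHyperbolicAgent, LogisticHyperbolicAgent
from .errors import ConfigError
from .scoring import score_session
from .task import TaskConfig, run_session

GROUPS = ("ARFID", "AN", "HC")
FLAG_COLUMNS = (
    "sensory_sensitivity",
    "fear_of_aversive_consequences",
    "lack_of_interest",
)


@dataclass(frozen=True)
class GroupSpec:
    """Size and (ln)k / age distribution parameters for one group."""

    n: int
    ln_k_mean: float
    ln_k_sd: float
    age_mean: float
    age_sd: float
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("group n must be positive")
        if self.ln_k_sd <= 0 or self.age_sd <= 0:
            raise ConfigError("group SDs must be positive")


def _default_groups() -> dict[str, GroupSpec]:
    return {
        "ARFID": GroupSpec(57, -6.1, 2.0, 17.42, 5.38, female_fraction=34 / 57),
        "AN": GroupSpec(28, -7.3, 1.7, 20.75, 3.76, female_fraction=1.0),
        "HC": GroupSpec(19, -5.4, 1.5, 21.32, 7.60, female_fraction=7 / 19),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort.

    ``presentation_marginals`` are the exact ARFID flag column sums in the
    order (sensory sensitivity, fear of aversive consequences, lack of
    interest).  ``mode`` selects direct (ln_k passed through) or behavioral
    (task played by agents) generation; behavioral noise is controlled by
    ``inverse_temperature`` (None = deterministic agents) and
    ``catch_error_rate``.
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    presentation_marginals: tuple[int, int, int] = (45, 18, 24)
    mode: str = "direct"
    inverse_temperature: Optional[float] = None
    catch_error_rate: float = 0.0
    age_range: tuple[float, float] = (10.0, 30.0)
    generate_sex: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "behavioral"):
            raise ConfigError(f"mode must be 'direct' or 'behavioral', got {self.mode!r}")
        if "ARFID" in self.groups:
            n_arfid = self.groups["ARFID"].n
            m = self.presentation_marginals
            if any(c < 0 or c > n_arfid for c in m):
                raise ConfigError("each presentation marginal must lie in [0, n_ARFID]")
            if sum(m) < n_arfid:
                raise ConfigError(
                    "presentation marginals sum to less than n_ARFID; "
                    "cannot give every participant a flag"
                )
        if not (0.0 <= self.catch_error_rate <= 1.0):
            raise ConfigError("catch_error_rate must lie in [0, 1]")
        lo, hi = self.age_range
        if lo >= hi:
            raise ConfigError("age_range must be an increasing pair")

    def to_dict(self) -> dict:
        return {
            "groups": {
                g: {
                    "n": s.n,
                    "ln_k_mean": s.ln_k_mean,
                    "ln_k_sd": s.ln_k_sd,
                    "age_mean": s.age_mean,
                    "age_sd": s.age_sd,
                    "female_fraction": s.female_fraction,
                }
                for g, s in self.groups.items()
            },
            "presentation_marginals": list(self.presentation_marginals),
            "mode": self.mode,
            "inverse_temperature": self.inverse_temperature,
            "catch_error_rate": self.catch_error_rate,
            "age_range": list(self.age_range),
            "generate_sex": self.generate_sex,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "groups" in d:
            d["groups"] = {g: GroupSpec(**s) for g, s in d["groups"].items()}
        if "presentation_marginals" in d:
            d["presentation_marginals"] = tuple(d["presentation_marginals"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass(frozen=True)
class Participant:
    """One synthetic participant."""

    id: str
    group: str
    age: float
    sex: Optional[str]
    sensory_sensitivity: int
    fear_of_aversive_consequences: int
    lack_of_interest: int
    ln_k: Optional[float] = None  # direct mode
    k_true: Optional[float] = None  # behavioral mode


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Sample Normal(mean, sd) truncated to [lo, hi] by resampling."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def allocate_presentation_flags(
    n: int, marginals: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    """Random n x 3 binary matrix with exact column sums and no all-zero row.

    Flags are first assigned per column by uniform sampling without
    replacement, then all-zero rows are repaired by moving one flag from a
    multi-flag row (preserving column sums).  Feasible whenever each
    marginal is <= n and the marginals sum to >= n.
    """
    if any(c < 0 or c > n for c in marginals) or sum(marginals) < n:
        raise ConfigError(f"infeasible flag marginals {marginals} for n={n}")
    flags = np.zeros((n, 3), dtype=int)
    for j, c in enumerate(marginals):
        flags[rng.choice(n, size=c, replace=False), j] = 1
    zero_rows = list(np.flatnonzero(flags.sum(axis=1) == 0))
    rng.shuffle(zero_rows)
    for r in zero_rows:
        donors = np.flatnonzero(flags.sum(axis=1) >= 2)
        donor = donors[rng.integers(donors.size)]
        col_options = np.flatnonzero(flags[donor])
        j = col_options[rng.integers(col_options.size)]
        flags[donor, j] = 0
        flags[r, j] = 1
    assert (flags.sum(axis=0) == np.asarray(marginals)).all()
    assert (flags.sum(axis=1) >= 1).all()
    return flags


def generate_cohort(spec: CohortSpec) -> list[Participant]:
    """Draw a full cohort from the spec, reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    participants: list[Participant] = []
    for group, gs in spec.groups.items():
        ages = _truncated_normal(rng, gs.age_mean, gs.age_sd, lo, hi, gs.n)
        ln_ks = rng.normal(gs.ln_k_mean, gs.ln_k_sd, size=gs.n)
        if spec.generate_sex:
            sexes = np.where(rng.random(gs.n) < gs.female_fraction, "female", "male")
        else:
            sexes = np.full(gs.n, None)
        if group == "ARFID":
            flags = allocate_presentation_flags(gs.n, spec.presentation_marginals, rng)
        else:
            flags = np.zeros((gs.n, 3), dtype=int)
        for i in range(gs.n):
            participants.append(
                Participant(
                    id=f"{group}-{i + 1:03d}",
                    group=group,
                    age=float(ages[i]),
                    sex=None if sexes[i] is None else str(sexes[i]),
                    sensory_sensitivity=int(flags[i, 0]),
                    fear_of_aversive_consequences=int(flags[i, 1]),
                    lack_of_interest=int(flags[i, 2]),
                    ln_k=float(ln_ks[i]) if spec.mode == "direct" else None,
                    k_true=float(math.exp(ln_ks[i])) if spec.mode == "behavioral" else None,
                )
            )
    return participants


def participants_to_frame(participants: list[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.id,
                "group": p.group,
                "age": p.age,
                "sex": p.sex,
                "sensory_sensitivity": p.sensory_sensitivity,
                "fear_of_aversive_consequences": p.fear_of_aversive_consequences,
                "lack_of_interest": p.lack_of_interest,
                "ln_k": p.ln_k,
                "k_true": p.k_true,
            }
        )
    return pd.DataFrame(rows)


def simulate_study(
    spec: CohortSpec,
    task_config: Optional[TaskConfig] = None,
    return_sessions: bool = False,
):
    """Generate a cohort and produce the analysis-ready tables.

    Returns ``(participants, scores)`` DataFrames joined on participant_id;
    with ``return_sessions=True`` the behavioral-mode SessionRecords are
    returned as a third element.

    Direct mode passes the sampled (ln)k straight through (every participant
    valid).  Behavioral mode builds a hyperbolic agent per participant
    (deterministic if ``spec.inverse_temperature`` is None, logistic
    otherwise), runs the adaptive task, scores the staircase and applies the
    catch-accuracy exclusion rule; excluded participants appear in the
    scores table with ``valid=False``.
    """
    participants = generate_cohort(spec)
    pframe = participants_to_frame(participants)

    if spec.mode == "direct":
        scores = pd.DataFrame(
            {
                "participant_id": pframe["participant_id"],
                "k": np.exp(pframe["ln_k"]),
                "ln_k": pframe["ln_k"],
                "catch_correct": 4,
                "catch_total": 4,
                "valid": True,
            }
        )
        if return_sessions:
            return pframe, scores, []
        return pframe, scores

    if task_config is None:
        raise ConfigError("behavioral mode requires a task_config")
    # independent child seed per participant, all below 2**31
    seed_seq = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s) % (2**31) for s in seed_seq.generate_state(len(participants))]
    sessions = []
    score_rows = []
    for p, s in zip(participants, child_seeds):
        if spec.inverse_temperature is None:
            agent = DeterministicHyperbolicAgent(p.k_true, spec.catch_error_rate)
        else:
            agent = LogisticHyperbolicAgent(
                p.k_true, spec.inverse_temperature, spec.catch_error_rate
            )
        session = run_session(agent, task_config, seed=s, participant_id=p.id)
        sessions.append(session)
        sc = score_session(session, task_config)
        row = {
            "participant_id": sc.participant_id,
            "k": sc.k,
            "ln_k": sc.ln_k,
            "catch_correct": sc.catch_correct,
            "catch_total": sc.catch_total,
            "valid": sc.valid,
        }
        for e in sc.profile.estimates:
            tag = f"d{int(e.delay_days)}"
            row[f"{tag}_indifference_point"] = e.indifference_point
            row[f"{tag}_k_d"] = e.k_d
        score_rows.append(row)
    scores = pd.DataFrame(score_rows)
    if return_sessions:
        return pframe, scores, sessions
    return pframe, scores
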