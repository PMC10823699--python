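"""File I/O: session logs, participant and score tables, configs, reports.

All CSVs are comma-separated UTF-8 with a header row and '.' decimals, and
start with a single comment line embedding the seed and a config
fingerprint so every artifact is traceable to the run that produced it.
Money columns serialize exactly (all staircase offers are dyadic rationals,
so their decimal expansions terminate).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .errors import ParseError
from .scoring import DiscountScore, score_choice_series
from .task import SessionRecord, TaskConfig

log = logging.getLogger("discountkit")

SESSION_COLUMNS = [
    "participant_id",
    "global_index",
    "is_catch",
    "delay_days",
    "present_offer",
    "future_offer",
    "choice",
    "correct",
]

SCORE_COLUMNS = ["participant_id", "k", "ln_k", "catch_correct", "catch_total", "valid"]


def fingerprint(obj: dict) -> str:
    """Short stable hash of a JSON-serializable config dict."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:12]


def _header_line(seed: Optional[int], fp: str) -> str:
    return f"# discountkit seed={seed} config={fp}\n"


def write_table(
    df: pd.DataFrame, path: str | Path, seed: Optional[int], config_fingerprint: str
) -> None:
    """Write a CSV with the provenance comment line prepended."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_line(seed, config_fingerprint))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# session logs
# ---------------------------------------------------------------------------

def sessions_to_frame(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """Flatten SessionRecords to one row per trial.

    Catch rows carry the two option amounts in present_offer/future_offer,
    their choice token in {a, b}, and the correct token; delay_days is empty.
    """
    rows = []
    for s in sessions:
        for trial, choice in s.trials:
            if trial.is_catch:
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "global_index": trial.global_index,
                        "is_catch": True,
                        "delay_days": None,
                        "present_offer": trial.catch.option_a[0],
                        "future_offer": trial.catch.option_b[0],
                        "choice": choice,
                        "correct": trial.catch.correct,
                    }
                )
            else:
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "global_index": trial.global_index,
                        "is_catch": False,
                        "delay_days": trial.delay_days,
                        "present_offer": trial.present_offer,
                        "future_offer": trial.future_offer,
                        "choice": choice,
                        "correct": None,
                    }
                )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def score_log_frame(df: pd.DataFrame, config: TaskConfig) -> list[DiscountScore]:
    """Score a session-log table (one row per trial) participant by participant.

    Raises ParseError naming the missing column on schema mismatch, or
    citing the 0-based row number on a malformed choice token.
    """
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"session log is missing column {col!r}")
    scores = []
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("global_index")
        series: dict[float, list[str]] = {d: [] for d in config.delays}
        catch_correct = 0
        catch_total = 0
        for row_idx, row in sub.iterrows():
            choice = row["choice"]
            if bool(row["is_catch"]):
                if choice not in ("a", "b"):
                    raise ParseError(
                        f"row {row_idx}: malformed catch choice token {choice!r}"
                    )
                catch_total += 1
                catch_correct += int(choice == row["correct"])
            else:
                if choice not in ("present", "future"):
                    raise ParseError(
                        f"row {row_idx}: malformed choice token {choice!r}"
                    )
                d = float(row["delay_days"])
                if d not in series:
                    raise ParseError(
                        f"row {row_idx}: delay {d} not in the task config"
                    )
                series[d].append(choice)
        scores.append(
            score_choice_series(series, config, catch_correct, catch_total, str(pid))
        )
    return scores


def scores_to_frame(scores: Sequence[DiscountScore]) -> pd.DataFrame:
    """Wide score table: k, ln_k, validity, plus per-delay (ip, k_d) columns."""
    rows = []
    for s in scores:
        row = {
            "participant_id": s.participant_id,
            "k": s.k,
            "ln_k": s.ln_k,
            "catch_correct": s.catch_correct,
            "catch_total": s.catch_total,
            "valid": s.valid,
        }
        for e in s.profile.estimates:
            tag = f"d{int(e.delay_days)}"
            row[f"{tag}_indifference_point"] = e.indifference_point
            row[f"{tag}_k_d"] = e.k_d
        rows.append(row)
    return pd.DataFrame(rows, columns=None if rows else SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# configs and reports
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file (by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(config, indent=2), encoding="utf-8")


def report_to_dict(ancova_results, pairwise, regression_results, power_result, meta=None):
    """Serialize the full analysis into one JSON-ready dict."""
    d = {
        "meta": meta or {},
        "ancova": {
            "F": ancova_results.F,
            "df_num": ancova_results.df_num,
            "df_den": ancova_results.df_den,
            "p": ancova_results.p_value,
            "eta_p2": ancova_results.eta_p2,
            "adjusted_means": {k: float(v) for k, v in ancova_results.adjusted_means.items()},
            "adjusted_se": {k: float(v) for k, v in ancova_results.adjusted_se.items()},
            "residual_variance": ancova_results.residual_variance,
            "covariate_coefficient": ancova_results.covariate_coefficient,
            "group_means": {k: float(v) for k, v in ancova_results.group_means.items()},
            "group_sds": {k: float(v) for k, v in ancova_results.group_sds.items()},
            "group_sizes": {k: int(v) for k, v in ancova_results.group_sizes.items()},
        },
        "pairwise": [
            {
                "contrast": list(pw.contrast),
                "difference": pw.difference,
                "se": pw.se,
                "t": pw.t,
                "df": pw.df,
                "p_uncorrected": pw.p_uncorrected,
                "p_bonferroni": pw.p_bonferroni,
                "hedges_g": pw.hedges_g,
            }
            for pw in pairwise
        ],
        "power": {
            "eta_p2_input": power_result.eta_p2_input,
            "f2": power_result.f2,
            "noncentrality": power_result.noncentrality,
            "df_num": power_result.df_num,
            "df_den": power_result.df_den,
            "critical_F": power_result.critical_F,
            "alpha": power_result.alpha,
            "power": power_result.power,
        },
    }
    if regression_results is not None:
        d["presentation_regression"] = {
            "coefficients": {k: float(v) for k, v in regression_results.coefficients.items()},
            "p_values": {k: float(v) for k, v in regression_results.p_values.items()},
            "F": regression_results.F,
            "p_overall": regression_results.p_overall,
            "r2": regression_results.r2,
            "adjusted_r2": regression_results.adjusted_r2,
        }
    return d


def save_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
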