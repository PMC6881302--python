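"""Reading and writing of the pipeline's file formats.

All tables are UTF-8, LF-terminated CSV with a mandatory header; missing
values (missed trials) are written as empty fields.  Trial indexing is
0-based everywhere, including on disk.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import pandas as pd
import yaml

from .fitting import FitResult
from .task import TaskConfig, TrialRecord, config_from_dict, config_to_dict

__all__ = [
    "TRIALS_COLUMNS",
    "write_trials",
    "read_trials",
    "sessions_from_trials",
    "write_fits",
    "read_fits",
    "load_task_config",
    "save_task_config",
]

TRIALS_COLUMNS = [
    "subject_id", "trial", "start_state", "choice", "advisor_id",
    "stock", "reward", "missed",
]

_INT_COLUMNS = ["trial", "start_state", "choice", "advisor_id", "stock", "missed"]


def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    out = trials[TRIALS_COLUMNS].copy()
    for col in ("choice", "advisor_id", "stock"):
        out[col] = out[col].astype("Int64")
    rewards = out["reward"].dropna()
    if len(rewards) and (rewards == rewards.round()).all():
        out["reward"] = out["reward"].astype("Int64")  # integer payouts
    out.to_csv(path, index=False, lineterminator="\n")


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file lacks columns: {sorted(missing)}")
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    df["subject_id"] = df["subject_id"].astype(str)
    return df[TRIALS_COLUMNS]


def sessions_from_trials(trials: pd.DataFrame) -> dict[str, list[TrialRecord]]:
    """Group a trials table into ordered per-subject TrialRecord lists."""
    sessions: dict[str, list[TrialRecord]] = {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial")
        records = []
        for row in sub.itertuples(index=False):
            missed = bool(row.missed)
            records.append(
                TrialRecord(
                    subject_id=str(row.subject_id),
                    trial=int(row.trial),
                    start_state=int(row.start_state),
                    choice=None if missed else int(row.choice),
                    advisor_id=None if missed else int(row.advisor_id),
                    stock=None if missed else int(row.stock),
                    reward=None if missed else float(row.reward),
                    missed=missed,
                )
            )
        sessions[str(sid)] = records
    return sessions


def fits_to_frame(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    rows = []
    for sid in sorted(fits):
        f = fits[sid]
        row = {
            "subject_id": sid,
            "alpha": f.map_params.alpha,
            "beta": f.map_params.beta,
            "lam": f.map_params.lam,
            "w": f.map_params.w,
            "pi": f.map_params.pi,
            "log_posterior": f.log_posterior,
            "log_likelihood": f.log_likelihood,
            "converged": int(f.converged),
        }
        for i in range(4):
            row[f"final_q_mf_{i}"] = float(f.final_q_mf[i])
        for i in range(4):
            row[f"final_q_mb_{i}"] = float(f.final_q_mb[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(fits: Mapping[str, FitResult], path: Union[str, Path]) -> None:
    fits_to_frame(fits).to_csv(path, index=False, lineterminator="\n")


def read_fits(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def fits_from_frame(df: pd.DataFrame) -> dict[str, FitResult]:
    """Rebuild FitResult objects from a fits table (inverse of fits_to_frame)."""
    import numpy as np

    from .agent import AgentParameters

    fits: dict[str, FitResult] = {}
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        fits[sid] = FitResult(
            subject_id=sid,
            map_params=AgentParameters(
                alpha=row.alpha, beta=row.beta, lam=row.lam, w=row.w, pi=row.pi
            ),
            log_posterior=float(getattr(row, "log_posterior", float("nan"))),
            log_likelihood=float(getattr(row, "log_likelihood", float("nan"))),
            n_restarts=0,
            converged=bool(getattr(row, "converged", True)),
            final_q_mf=np.array([getattr(row, f"final_q_mf_{i}") for i in range(4)]),
            final_q_mb=np.array([getattr(row, f"final_q_mb_{i}") for i in range(4)]),
        )
    return fits


def load_task_config(path: Union[str, Path]) -> TaskConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_task_config(config: TaskConfig, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
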