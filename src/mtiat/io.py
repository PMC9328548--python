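"""Reading and writing trajectory logs, trial tables and flat config files.

The trajectory log is a long-format CSV with one row per cursor sample
(columns ``subject, block, trial, t_ms, x, y``); the trial table is one row
per trial (``subject, block, trial, condition, congruency, response,
correct, rt_ms`` plus any extra columns the producer adds).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectory import RawTrajectory

TRAJECTORY_COLUMNS = ["subject", "block", "trial", "t_ms", "x", "y"]
TRIAL_COLUMNS = ["subject", "block", "trial", "condition", "congruency", "response", "correct", "rt_ms"]


class ParseError(ValueError):
    """A malformed input file."""


def write_trajectory_log(trajectories: list[RawTrajectory], path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "subject": tr.subject,
                    "block": tr.block,
                    "trial": tr.trial,
                    "t_ms": tr.t,
                    "x": tr.x,
                    "y": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    return path


def read_trajectory_log(path: str | Path) -> list[RawTrajectory]:
    """Read a long-format trajectory CSV into per-trial objects.

    Rows are grouped by ``(subject, block, trial)`` in file order; a trial
    with non-increasing timestamps raises :class:`ParseError` naming it.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out: list[RawTrajectory] = []
    for key, grp in frame.groupby(["subject", "block", "trial"], sort=False):
        t = grp["t_ms"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ParseError(f"{path}: non-monotone timestamps in trial {key}")
        try:
            out.append(
                RawTrajectory(
                    subject=str(key[0]),
                    block=int(key[1]),
                    trial=int(key[2]),
                    t=t,
                    x=grp["x"].to_numpy(float),
                    y=grp["y"].to_numpy(float),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: trial {key}: {exc}") from exc
    return out


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ParseError(f"trial table missing columns {missing}")
    trials.to_csv(path, index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return frame


def write_config(mapping: dict, path: str | Path) -> Path:
    """Write a flat key-value configuration file (YAML)."""
    path = Path(path)
    flat = {k: (list(v) if isinstance(v, tuple) else v) for k, v in mapping.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)
    return path


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
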