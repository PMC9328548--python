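"""Containers for raw and normalized cursor trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawTrajectory:
    """One trial's sampled cursor path.

    ``t`` holds millisecond timestamps (strictly increasing, first sample at
    stimulus onset = 0); ``x``/``y`` are screen-pixel coordinates with y
    increasing downward, unless produced by :func:`mtiat.preprocess.space_normalize`
    (then normalized units with y increasing upward; see ``normalized``).
    """

    subject: str
    block: int
    trial: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if self.t[0] != 0:
            raise ValueError("timestamps must start at stimulus onset (t=0)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def key(self) -> tuple:
        return (self.subject, self.block, self.trial)

    @classmethod
    def _unchecked(cls, subject, block, trial, t, x, y, normalized=False):
        """Construct without re-validating arrays the caller just built.

        Only for internal producers (the simulator) whose output satisfies
        the invariants by construction.
        """
        obj = object.__new__(cls)
        obj.subject = subject
        obj.block = block
        obj.trial = trial
        obj.t = t
        obj.x = x
        obj.y = y
        obj.normalized = normalized
        return obj


@dataclass
class NormalizedTrajectory:
    """A 101-step, space-normalized trajectory with its map back to real time.

    Step 0 sits at the origin (the start button); coordinates are isotropic
    units in which the response-box row lies at y = 1.  ``step_times`` gives
    the real time in ms of each step (``step_times[0] = 0``,
    ``step_times[-1] = response_time``).
    """

    subject: str
    block: int
    trial: int
    x: np.ndarray
    y: np.ndarray
    step_times: np.ndarray
    initiation_time: float
    response_time: float
    remapped: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.step_times = np.asarray(self.step_times, dtype=float)
        n = len(self.x)
        if not (n == len(self.y) == len(self.step_times)):
            raise ValueError("x, y, step_times must have equal length")
        if np.any(np.diff(self.step_times) < 0):
            raise ValueError("step_times must be non-decreasing")

    @property
    def n_steps(self) -> int:
        return len(self.x)

    @property
    def key(self) -> tuple:
        return (self.subject, self.block, self.trial)


@dataclass
class NormalizedBatch:
    """Stacked normalized trajectories sharing a common step count.

    Row ``i`` of the arrays corresponds to row ``i`` of ``keys`` (columns
    ``subject, block, trial``).  This is the fast path used by the metric
    routines; :func:`from_list` / :func:`to_list` convert to and from
    per-trial objects.
    """

    keys: "object"  # pandas.DataFrame
    x: np.ndarray
    y: np.ndarray
    step_times: np.ndarray
    initiation_time: np.ndarray
    response_time: np.ndarray
    remapped: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.remapped is None:
            self.remapped = np.zeros(len(self.x), dtype=bool)

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_list(cls, trajectories: list[NormalizedTrajectory]) -> "NormalizedBatch":
        import pandas as pd

        if not trajectories:
            raise ValueError("empty trajectory list")
        keys = pd.DataFrame(
            [(tr.subject, tr.block, tr.trial) for tr in trajectories],
            columns=["subject", "block", "trial"],
        )
        return cls(
            keys=keys,
            x=np.stack([tr.x for tr in trajectories]),
            y=np.stack([tr.y for tr in trajectories]),
            step_times=np.stack([tr.step_times for tr in trajectories]),
            initiation_time=np.array([tr.initiation_time for tr in trajectories], float),
            response_time=np.array([tr.response_time for tr in trajectories], float),
            remapped=np.array([tr.remapped for tr in trajectories], bool),
        )

    def to_list(self) -> list[NormalizedTrajectory]:
        out = []
        for i, row in enumerate(self.keys.itertuples(index=False)):
            out.append(
                NormalizedTrajectory(
                    subject=row.subject,
                    block=int(row.block),
                    trial=int(row.trial),
                    x=self.x[i],
                    y=self.y[i],
                    step_times=self.step_times[i],
                    initiation_time=float(self.initiation_time[i]),
                    response_time=float(self.response_time[i]),
                    remapped=bool(self.remapped[i]),
                )
            )
        return out
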