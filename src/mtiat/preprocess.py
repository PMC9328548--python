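"""Trajectory preprocessing: initiation detection, normalization, filtering.

The chain mirrors standard mouse-tracking practice: detect movement onset,
translate the start to the origin and rescale both axes by the same factor
(the vertical start-to-box distance, so the response row lies at y = 1, with
the y axis flipped to mathematical orientation), time-normalize to 101 steps
by linear interpolation over real time, and mirror left-ending paths so all
trajectories terminate at the top-right response.  Trial exclusions are then
applied in a fixed order: incorrect trials, reaction-time outliers beyond
mean +/- 3 SD, and initiation times longer than 500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig, CRITICAL_BLOCKS, ConfigurationError
from .trajectory import NormalizedBatch, NormalizedTrajectory, RawTrajectory

N_STEPS = 101
IT_MAX_MS = 500.0
RT_SD_CRITERION = 3.0


def detect_initiation(raw: RawTrajectory, eps: float = 0.0) -> tuple[float, bool]:
    """Movement-onset latency in ms.

    Returns ``(it, moved)`` where ``it`` is the timestamp of the first
    sample whose Euclidean displacement from the first sample exceeds
    ``eps`` (default 0: any movement).  If the cursor never moves, ``it``
    is the final timestamp and ``moved`` is False.
    """
    disp = np.hypot(raw.x - raw.x[0], raw.y - raw.y[0])
    moved = np.nonzero(disp > eps)[0]
    if len(moved) == 0:
        return float(raw.t[-1]), False
    return float(raw.t[moved[0]]), True


def space_normalize(raw: RawTrajectory, design: DesignConfig) -> RawTrajectory:
    """Translate the start to (0, 0) and rescale isotropically.

    Both axes are divided by the same factor, the vertical distance in px
    from the start position to the response-box row, so the box row lies at
    y = 1; the y axis is flipped so upward motion is positive.  Being
    affine, the map preserves straight lines, angles and ratios of
    distances.
    """
    sx, sy = design.start_pos
    scale = sy - 0.5 * (design.left_box[1] + design.right_box[1])
    if scale <= 0:
        raise ConfigurationError("start-to-box vertical distance must be positive")
    return RawTrajectory(
        subject=raw.subject,
        block=raw.block,
        trial=raw.trial,
        t=raw.t.copy(),
        x=(raw.x - sx) / scale,
        y=(sy - raw.y) / scale,
        normalized=True,
    )


def time_normalize(
    raw: RawTrajectory, n_steps: int = N_STEPS, initiation_time: float | None = None
) -> NormalizedTrajectory:
    """Resample to ``n_steps`` equally spaced real-time points.

    Coordinates are linearly interpolated at times ``j * rt / (n_steps-1)``;
    endpoints are preserved exactly and ``step_times`` records the real time
    of each step.
    """
    if raw.n_samples < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    rt = float(raw.t[-1])
    q = np.linspace(0.0, rt, n_steps)
    if initiation_time is None:
        initiation_time, _ = detect_initiation(raw)
    x = np.interp(q, raw.t, raw.x)
    y = np.interp(q, raw.t, raw.y)
    # endpoints exactly
    x[0], y[0] = raw.x[0], raw.y[0]
    x[-1], y[-1] = raw.x[-1], raw.y[-1]
    return NormalizedTrajectory(
        subject=raw.subject,
        block=raw.block,
        trial=raw.trial,
        x=x,
        y=y,
        step_times=q,
        initiation_time=float(initiation_time),
        response_time=rt,
    )


def remap_to_right(traj: NormalizedTrajectory) -> NormalizedTrajectory:
    """Mirror a left-ending trajectory so it terminates on the right.

    Idempotent: paths already ending at x >= 0 are returned unchanged.
    """
    if traj.x[-1] >= 0:
        return traj
    return NormalizedTrajectory(
        subject=traj.subject,
        block=traj.block,
        trial=traj.trial,
        x=-traj.x,
        y=traj.y.copy(),
        step_times=traj.step_times.copy(),
        initiation_time=traj.initiation_time,
        response_time=traj.response_time,
        remapped=True,
    )


def preprocess_trajectory(
    raw: RawTrajectory, design: DesignConfig, n_steps: int = N_STEPS, eps: float = 0.0
) -> NormalizedTrajectory:
    """Full per-trial chain: onset, space-normalize, 101 steps, remap."""
    it, _ = detect_initiation(raw, eps=eps)
    return remap_to_right(time_normalize(space_normalize(raw, design), n_steps, it))


def preprocess_batch(
    trajectories: list[RawTrajectory],
    design: DesignConfig,
    n_steps: int = N_STEPS,
    eps: float = 0.0,
) -> NormalizedBatch:
    """Vectorized preprocessing for uniformly sampled trajectories.

    Requires every trial to be sampled on the same regular grid (the
    experiment's 100 Hz clock); falls back to the per-trial path otherwise.
    Produces results identical to :func:`preprocess_trajectory`.
    """
    dt = design.sample_interval
    n = len(trajectories)
    lengths = np.array([tr.n_samples for tr in trajectories])
    all_t = np.concatenate([tr.t for tr in trajectories])
    ends = np.cumsum(lengths)
    d = np.diff(all_t)
    boundary = np.zeros(len(d), bool)
    boundary[ends[:-1] - 1] = True
    uniform = lengths.min() >= 2 and np.all(np.abs(d[~boundary] - dt) < 1e-9)
    if not uniform:
        return NormalizedBatch.from_list(
            [preprocess_trajectory(tr, design, n_steps, eps) for tr in trajectories]
        )
    lmax = lengths.max()
    all_x = np.concatenate([tr.x for tr in trajectories])
    all_y = np.concatenate([tr.y for tr in trajectories])
    last_x = all_x[ends - 1]
    last_y = all_y[ends - 1]
    # pad each row with its final position
    X = np.repeat(last_x[:, None], lmax, axis=1)
    Y = np.repeat(last_y[:, None], lmax, axis=1)
    rows_flat = np.repeat(np.arange(n), lengths)
    cols_flat = np.arange(len(all_x)) - np.repeat(ends - lengths, lengths)
    X[rows_flat, cols_flat] = all_x
    Y[rows_flat, cols_flat] = all_y

    sx, sy = design.start_pos
    scale = sy - 0.5 * (design.left_box[1] + design.right_box[1])
    if scale <= 0:
        raise ConfigurationError("start-to-box vertical distance must be positive")
    X = (X - sx) / scale
    Y = (sy - Y) / scale

    # initiation: first sample displaced from the start (threshold eps)
    disp = np.hypot(X - X[:, :1], Y - Y[:, :1])
    movedmask = disp > eps / scale
    any_moved = movedmask.any(axis=1)
    first = np.where(any_moved, movedmask.argmax(axis=1), lengths - 1)
    it = first * dt

    rt = (lengths - 1) * dt
    # linear interpolation on the uniform grid at n_steps query times
    frac_steps = np.linspace(0.0, 1.0, n_steps)[None, :] * (lengths - 1)[:, None]
    i0 = np.floor(frac_steps).astype(int)
    i1 = np.minimum(i0 + 1, (lengths - 1)[:, None])
    w = frac_steps - i0
    rows = np.arange(n)[:, None]
    qx = (1 - w) * X[rows, i0] + w * X[rows, i1]
    qy = (1 - w) * Y[rows, i0] + w * Y[rows, i1]
    qx[:, 0], qy[:, 0] = X[:, 0], Y[:, 0]
    qx[:, -1] = X[rows[:, 0], lengths - 1]
    qy[:, -1] = Y[rows[:, 0], lengths - 1]
    step_times = frac_steps * dt

    flip = qx[:, -1] < 0
    qx[flip] = -qx[flip]

    keys = pd.DataFrame(
        [(tr.subject, tr.block, tr.trial) for tr in trajectories],
        columns=["subject", "block", "trial"],
    )
    return NormalizedBatch(
        keys=keys,
        x=qx,
        y=qy,
        step_times=step_times,
        initiation_time=it.astype(float),
        response_time=rt.astype(float),
        remapped=flip,
    )


# ---------------------------------------------------------------------------
# trial exclusion


@dataclass
class ExclusionReport:
    """Per-condition exclusion bookkeeping for the critical blocks."""

    frame: pd.DataFrame  # per congruency: counts and percentage excluded

    @property
    def pct_excluded(self) -> pd.Series:
        return self.frame.set_index("congruency")["pct_excluded"]

    def to_json(self) -> str:
        return self.frame.to_json(orient="records")


def filter_trials(
    records: pd.DataFrame,
    sd_scope: str = "subject",
    it_max: float = IT_MAX_MS,
    sd_criterion: float = RT_SD_CRITERION,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules to critical-block trial records.

    ``records`` needs columns ``subject, congruency, correct, rt_ms, it_ms``
    restricted to the critical blocks.  Rules apply in a fixed order:

    1. incorrect trials;
    2. reaction times outside mean +/- ``sd_criterion`` SD, the mean and SD
       computed over each subject's remaining critical trials
       (``sd_scope='pooled'`` computes them over all subjects);
    3. initiation times strictly longer than ``it_max`` ms.

    Returns the kept rows plus an :class:`ExclusionReport`; the returned
    frame carries an ``exclusion_reason`` column on the *input* index via
    ``report.frame`` percentages.
    """
    if len(records) == 0:
        raise ValueError("no critical-block trials to filter")
    if sd_scope not in ("subject", "pooled"):
        raise ValueError("sd_scope must be 'subject' or 'pooled'")
    rec = records.copy()
    rec["exclusion_reason"] = "none"

    rec.loc[~rec["correct"].astype(bool), "exclusion_reason"] = "incorrect"
    remaining = rec["exclusion_reason"] == "none"

    grouping = rec.loc[remaining].groupby("subject")["rt_ms"] if sd_scope == "subject" else None
    if sd_scope == "subject":
        mean = grouping.transform("mean")
        sd = grouping.transform("std")
    else:
        mean = pd.Series(rec.loc[remaining, "rt_ms"].mean(), index=rec.index[remaining])
        sd = pd.Series(rec.loc[remaining, "rt_ms"].std(), index=rec.index[remaining])
    sd = sd.fillna(0.0)
    lo = mean - sd_criterion * sd
    hi = mean + sd_criterion * sd
    rt = rec.loc[remaining, "rt_ms"]
    outlier = (rt < lo) | (rt > hi)
    rec.loc[outlier[outlier].index, "exclusion_reason"] = "rt_outlier"

    remaining = rec["exclusion_reason"] == "none"
    too_long = remaining & (rec["it_ms"] > it_max)
    rec.loc[too_long, "exclusion_reason"] = "it_too_long"

    rec["excluded"] = rec["exclusion_reason"] != "none"

    rows = []
    for cond, grp in rec.groupby("congruency"):
        n = len(grp)
        rows.append(
            dict(
                congruency=cond,
                n_total=n,
                n_incorrect=int((grp["exclusion_reason"] == "incorrect").sum()),
                n_rt_outlier=int((grp["exclusion_reason"] == "rt_outlier").sum()),
                n_it_too_long=int((grp["exclusion_reason"] == "it_too_long").sum()),
                n_kept=int((~grp["excluded"]).sum()),
                pct_excluded=100.0 * grp["excluded"].sum() / n,
            )
        )
    report = ExclusionReport(frame=pd.DataFrame(rows))
    kept = rec[~rec["excluded"]].drop(columns=["excluded"])
    return kept, report


def critical_records(meta: pd.DataFrame, batch: NormalizedBatch) -> pd.DataFrame:
    """Join trial metadata with per-trial it/rt from preprocessing."""
    timing = batch.keys.copy()
    timing["it_ms"] = batch.initiation_time
    timing["rt_traj_ms"] = batch.response_time
    merged = meta.merge(timing, on=["subject", "block", "trial"], how="inner")
    return merged[merged["block"].isin(CRITICAL_BLOCKS)].reset_index(drop=True)
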