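"""Per-trial mouse-tracking metrics on 101-step normalized trajectories.

Geometry (MD, AUC) is measured against the idealised straight segment from
the trajectory's start to its end point; after remapping that segment runs
toward the top-right response, and the signed conventions put positive
values on the side of the non-chosen (left) response.  Dynamic metrics are
finite differences of the time-normalized x series (dimensionless,
per-step); their ``*_time`` companions map the first step attaining the
maximum back to real time through ``step_times``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import NormalizedBatch, NormalizedTrajectory


class DegenerateTrajectoryError(ValueError):
    """Start and end point coincide; the ideal line is undefined."""


@dataclass(frozen=True)
class MetricSet:
    """All metrics of one trial (times in ms, geometry in normalized units)."""

    it: float
    rt: float
    md: float
    md_time: float
    auc: float
    vel_max: float
    vel_max_time: float
    acc_max: float
    acc_max_time: float
    xpos_flips: int
    entropy: float
    entropy_defined: bool


def _as_batch(traj: NormalizedTrajectory | NormalizedBatch) -> tuple[NormalizedBatch, bool]:
    if isinstance(traj, NormalizedBatch):
        return traj, False
    return NormalizedBatch.from_list([traj]), True


def _signed_deviation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of each step from the start-end chord.

    Positive on the left of the start-to-end direction, i.e. toward the
    non-chosen response after remapping.
    """
    ex = x[:, -1:] - x[:, :1]
    ey = y[:, -1:] - y[:, :1]
    norm = np.hypot(ex, ey)
    if np.any(norm == 0):
        raise DegenerateTrajectoryError("trajectory start and end coincide")
    cross = ex * (y - y[:, :1]) - ey * (x - x[:, :1])
    return cross / norm


def max_deviation(traj: NormalizedTrajectory | NormalizedBatch):
    """Maximum deviation: ``(md, md_step, md_time)``.

    ``md`` is the signed perpendicular distance with the largest magnitude,
    ``md_step`` the first step attaining it, ``md_time`` that step's real
    time in ms.
    """
    batch, single = _as_batch(traj)
    dev = _signed_deviation(batch.x, batch.y)
    step = np.abs(dev).argmax(axis=1)
    rows = np.arange(len(batch))
    md = dev[rows, step]
    md_time = batch.step_times[rows, step]
    if single:
        return float(md[0]), int(step[0]), float(md_time[0])
    return md, step, md_time


def area_under_curve(traj: NormalizedTrajectory | NormalizedBatch):
    """Signed area between the trajectory polyline and the ideal segment.

    Computed by the shoelace formula on the polygon formed by the
    trajectory plus the reversed ideal segment; area on the non-chosen
    (left) side counts positive, overshoot on the chosen side negative.
    """
    batch, single = _as_batch(traj)
    x, y = batch.x, batch.y
    ex = x[:, -1] - x[:, 0]
    ey = y[:, -1] - y[:, 0]
    if np.any(np.hypot(ex, ey) == 0):
        raise DegenerateTrajectoryError("trajectory start and end coincide")
    # closed loop p0..pN -> p0 (the return edge is the ideal segment)
    xs = np.concatenate([x, x[:, :1]], axis=1)
    ys = np.concatenate([y, y[:, :1]], axis=1)
    shoelace = np.sum(xs[:, :-1] * ys[:, 1:] - xs[:, 1:] * ys[:, :-1], axis=1)
    auc = -0.5 * shoelace
    if single:
        return float(auc[0])
    return auc


def x_dynamics(traj: NormalizedTrajectory | NormalizedBatch):
    """x-velocity and x-acceleration maxima with first-occurrence times.

    ``v_i = x_{i+1} - x_i`` and ``a_i = v_{i+1} - v_i`` on the
    time-normalized series; maxima are over signed values and ``*_time``
    is the real time of the first step attaining the maximum.
    """
    batch, single = _as_batch(traj)
    v = np.diff(batch.x, axis=1)
    a = np.diff(v, axis=1)
    rows = np.arange(len(batch))
    iv = v.argmax(axis=1)
    ia = a.argmax(axis=1)
    vel_max = v[rows, iv]
    acc_max = a[rows, ia]
    vel_max_time = batch.step_times[rows, iv]
    acc_max_time = batch.step_times[rows, ia]
    if single:
        return float(vel_max[0]), float(vel_max_time[0]), float(acc_max[0]), float(acc_max_time[0])
    return vel_max, vel_max_time, acc_max, acc_max_time


def x_flips(traj: NormalizedTrajectory | NormalizedBatch):
    """Directional changes along x: sign reversals of nonzero steps."""
    batch, single = _as_batch(traj)
    v = np.diff(batch.x, axis=1)
    s = np.sign(v)
    n, m = s.shape
    # carry the last nonzero sign forward, then count sign changes
    idx = np.where(s != 0, np.arange(m)[None, :], -1)
    last = np.maximum.accumulate(idx, axis=1)
    rows = np.arange(n)[:, None]
    prev = np.where(last >= 0, s[rows, np.maximum(last, 0)], 0.0)
    prev_before = np.concatenate([np.zeros((n, 1)), prev[:, :-1]], axis=1)
    flips = ((s != 0) & (prev_before != 0) & (s != prev_before)).sum(axis=1)
    if single:
        return int(flips[0])
    return flips


def sample_entropy(
    traj: NormalizedTrajectory | NormalizedBatch, m: int = 3, r_frac: float = 0.2
):
    """Sample entropy of the first-differenced x series.

    Template length ``m``, tolerance ``r = r_frac * SD`` of the differenced
    series, Chebyshev distance, self-matches excluded (both template sets
    range over the same ``N - m`` offsets).  Returns ``(entropy, defined)``;
    a zero-variance series or zero match count yields ``(nan, False)``.
    """
    batch, single = _as_batch(traj)
    ents = np.empty(len(batch))
    defined = np.empty(len(batch), dtype=bool)
    for i in range(len(batch)):
        ents[i], defined[i] = _sampen_1d(np.diff(batch.x[i]), m, r_frac)
    if single:
        return float(ents[0]), bool(defined[0])
    return ents, defined


def _sampen_1d(series: np.ndarray, m: int, r_frac: float) -> tuple[float, bool]:
    n = len(series)
    if n <= m + 1:
        return np.nan, False
    sd = series.std()
    if sd == 0:
        return np.nan, False
    r = r_frac * sd
    n_templates = n - m  # offsets valid for both m and m+1 templates
    # running Chebyshev distance over windows of length m and m+1
    d = np.abs(series[:, None] - series[None, :])
    cheb = d[:n_templates, :n_templates].copy()
    for lag in range(1, m):
        np.maximum(cheb, d[lag : lag + n_templates, lag : lag + n_templates], out=cheb)
    iu = np.triu_indices(n_templates, k=1)
    b = int((cheb[iu] <= r).sum())
    np.maximum(cheb, d[m : m + n_templates, m : m + n_templates], out=cheb)
    a = int((cheb[iu] <= r).sum())
    if a == 0 or b == 0:
        return np.nan, False
    return float(-np.log(a / b)), True


def compute_metric_set(traj: NormalizedTrajectory, m: int = 3, r_frac: float = 0.2) -> MetricSet:
    """All metrics for a single preprocessed trial."""
    md, _, md_time = max_deviation(traj)
    auc = area_under_curve(traj)
    vel_max, vel_max_time, acc_max, acc_max_time = x_dynamics(traj)
    flips = x_flips(traj)
    ent, ok = sample_entropy(traj, m=m, r_frac=r_frac)
    return MetricSet(
        it=traj.initiation_time,
        rt=traj.response_time,
        md=md,
        md_time=md_time,
        auc=auc,
        vel_max=vel_max,
        vel_max_time=vel_max_time,
        acc_max=acc_max,
        acc_max_time=acc_max_time,
        xpos_flips=flips,
        entropy=ent,
        entropy_defined=ok,
    )


def compute_metrics(
    trajectories: NormalizedBatch | list[NormalizedTrajectory],
    entropy: bool = True,
) -> pd.DataFrame:
    """Tidy per-trial metrics table (one row per trial).

    ``entropy=False`` skips the quadratic-cost sample-entropy column for
    large simulation sweeps where it is not analysed.
    """
    batch = trajectories if isinstance(trajectories, NormalizedBatch) else NormalizedBatch.from_list(trajectories)
    md, _, md_time = max_deviation(batch)
    auc = area_under_curve(batch)
    vel_max, vel_max_time, acc_max, acc_max_time = x_dynamics(batch)
    flips = x_flips(batch)
    out = batch.keys.copy()
    out["it_ms"] = batch.initiation_time
    out["rt_ms"] = batch.response_time
    out["md"] = md
    out["md_time_ms"] = md_time
    out["auc"] = auc
    out["vel_max"] = vel_max
    out["vel_max_time_ms"] = vel_max_time
    out["acc_max"] = acc_max
    out["acc_max_time_ms"] = acc_max_time
    out["xpos_flips"] = flips
    if entropy:
        ent, ok = sample_entropy(batch)
        out["entropy"] = ent
        out["entropy_defined"] = ok
    return out
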