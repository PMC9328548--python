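"""Synthetic race-IAT sessions: keyboard latencies and 100 Hz cursor paths.

A single latent implicit-bias strength ``b`` per subject drives both tasks:

* keyboard latencies are log-normal, with ``log(rt) ~ N(base_log_rt + b, rt_sd)``
  on stereotype-incongruent trials and no shift on congruent ones;
* cursor initiation latency gains ``kappa * b`` ms on incongruent trials;
* after movement onset the per-step heading is a normalized blend
  ``(1 - w_t) * u_target + w_t * u_opposite`` with
  ``w_t = w0 * exp(-t / tau)`` and ``w0 = w_base + lambda * b`` on
  incongruent trials, plus Gaussian heading noise, so the path is smoothly
  attracted toward the incorrect response early in the movement and
  straightens as the attraction decays.  Speed follows a bell-shaped profile
  over a constant floor, which guarantees arrival.

Because the attraction decays continuously and the only stochasticity is
small per-step heading noise, maximum-deviation values are unimodal within
each congruency condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignConfig, build_schedule, _rng
from .trajectory import RawTrajectory


class GenerationError(RuntimeError):
    """A simulated trajectory failed to terminate within the hard cap."""


@dataclass(frozen=True)
class SubjectParams:
    """Latent parameters of one simulated subject.

    ``bias`` is the unitless implicit-bias strength shared across tasks
    (>= 0); ``base_log_rt``/``rt_sd`` parameterise the keyboard log-normal
    in log-ms units; ``base_it``/``it_sd`` the mouse initiation-time normal
    in ms.  Error rates are per-trial probabilities by congruency.
    """

    subject_id: str
    bias: float
    base_log_rt: float
    rt_sd: float
    base_it: float
    it_sd: float
    error_rate_congruent: float
    error_rate_incongruent: float

    def __post_init__(self) -> None:
        if self.bias < 0:
            raise ValueError("bias must be >= 0")
        if self.rt_sd <= 0 or self.it_sd <= 0:
            raise ValueError("rt_sd and it_sd must be > 0")
        for p in (self.error_rate_congruent, self.error_rate_incongruent):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass(frozen=True)
class TrajectoryParams:
    """Constants of the cursor-movement model (units in doc strings)."""

    w_base: float = 0.18  # baseline attraction weight toward the opposite box
    attraction_gain: float = 0.45  # lambda: extra weight per unit bias (incongruent)
    it_gain: float = 120.0  # kappa: ms of extra initiation latency per unit bias
    tau: float = 250.0  # ms, exponential decay constant of the attraction
    conflict_persistence: float = 3.0  # relative tau increase per unit bias (incongruent)
    conflict_slowdown: float = 0.35  # relative speed reduction per unit bias (incongruent)
    heading_noise_sd: float = 0.15  # rad of heading noise per 10 ms step
    v_base: float = 0.60  # px/ms floor speed
    v_peak: float = 0.90  # px/ms amplitude of the bell-shaped speed profile
    v_peak_time: float = 350.0  # ms after movement onset at which speed peaks
    v_width: float = 180.0  # ms, SD of the speed bell
    max_duration: float = 10000.0  # ms hard cap on simulated movement


@dataclass(frozen=True)
class PopulationConfig:
    """Population distributions the per-subject parameters are drawn from.

    ``bias_mean``/``bias_sd`` parameterise the latent pro-White bias
    (normal, clipped at 0).  Keyboard error rates are
    ``error_rate_base`` (congruent) and ``error_rate_base +
    error_bias_gain * bias`` (incongruent); the mouse task uses the same
    rates scaled by ``mouse_error_scale``, reflecting the higher accuracy
    observed when responses are selected by reaching rather than keypress.
    """

    bias_mean: float = 0.27
    bias_sd: float = 0.10
    base_log_rt_mean: float = math.log(700.0)
    base_log_rt_sd: float = 0.12
    rt_sd: float = 0.22
    base_it_mean: float = 240.0
    base_it_sd: float = 30.0
    it_sd: float = 45.0
    error_rate_base: float = 0.04
    error_bias_gain: float = 0.22
    mouse_error_scale: float = 0.4


def draw_subject_params(
    population: PopulationConfig, seed: int, subject_index: int
) -> tuple[SubjectParams, SubjectParams]:
    """Draw one subject's latent parameters (keyboard variant, mouse variant).

    Both variants share the same ``bias``; the mouse variant only rescales
    the error rates.
    """
    rng = _rng(seed, subject_index, 0)
    bias = max(0.0, rng.normal(population.bias_mean, population.bias_sd))
    base_log_rt = rng.normal(population.base_log_rt_mean, population.base_log_rt_sd)
    base_it = max(50.0, rng.normal(population.base_it_mean, population.base_it_sd))
    err_c = population.error_rate_base
    err_i = min(1.0, population.error_rate_base + population.error_bias_gain * bias)
    kb = SubjectParams(
        subject_id=f"S{subject_index:03d}",
        bias=bias,
        base_log_rt=base_log_rt,
        rt_sd=population.rt_sd,
        base_it=base_it,
        it_sd=population.it_sd,
        error_rate_congruent=err_c,
        error_rate_incongruent=err_i,
    )
    scale = population.mouse_error_scale
    mouse = replace(
        kb,
        error_rate_congruent=err_c * scale,
        error_rate_incongruent=err_i * scale,
    )
    return kb, mouse


# ---------------------------------------------------------------------------
# keyboard task


def simulate_keyboard_session(
    params: SubjectParams,
    schedule: pd.DataFrame,
    seed: int,
    subject_index: int = 0,
) -> pd.DataFrame:
    """Simulate one keyboard session over ``schedule``.

    ``log(rt)`` is normal with a ``+bias`` shift on incongruent trials;
    correctness is Bernoulli with the congruency's error rate.  Identical
    seed and schedule reproduce the table exactly.
    """
    rng = _rng(seed, subject_index, 1)
    n = len(schedule)
    incong = (schedule["congruency"] == "incongruent").to_numpy()
    mu = params.base_log_rt + params.bias * incong
    rt = np.exp(rng.normal(mu, params.rt_sd))
    err = np.where(incong, params.error_rate_incongruent, params.error_rate_congruent)
    correct = rng.random(n) >= err
    out = schedule.copy()
    out.insert(0, "subject", params.subject_id)
    out["rt_ms"] = rt
    out["correct"] = correct
    side = out["correct_side"].to_numpy()
    other = np.where(side == "left", "right", "left")
    out["response"] = np.where(correct, side, other)
    return out


# ---------------------------------------------------------------------------
# mouse task


def _movement_targets(design: DesignConfig, chosen_side: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    left = np.array(design.left_box, float)
    right = np.array(design.right_box, float)
    chosen = np.where(chosen_side[:, None] == "left", left, right)
    opposite = np.where(chosen_side[:, None] == "left", right, left)
    return chosen, opposite


NOISE_CHUNK_STEPS = 384  # heading-noise columns drawn per block


def _mouse_trial_arrays(params, schedule, design, tp, seed, subject_index):
    """Per-trial random draws and dynamic constants for one session.

    All draws come from the subject's mouse stream in a fixed order and
    with fixed shapes (uniforms for response choice, standard normals for
    initiation times, then (n_trials, 384)-column blocks of heading noise
    drawn on demand), so any single trial can be reproduced by
    regenerating the same blocks and slicing its row.
    """
    dt = design.sample_interval
    n = len(schedule)
    incong = (schedule["congruency"] == "incongruent").to_numpy()
    err = np.where(incong, params.error_rate_incongruent, params.error_rate_congruent)

    r = _rng(seed, subject_index, 2)
    chosen_correct = r.random(n) >= err
    mu_it = params.base_it + tp.it_gain * params.bias * incong
    it = np.maximum(mu_it + params.it_sd * r.standard_normal(n), dt)
    noise = r.standard_normal((n, NOISE_CHUNK_STEPS)) * tp.heading_noise_sd

    side = schedule["correct_side"].to_numpy()
    other = np.where(side == "left", "right", "left")
    response_side = np.where(chosen_correct, side, other)
    target, opposite = _movement_targets(design, response_side)
    arrays = dict(
        chosen_correct=chosen_correct,
        it=it,
        noise=noise,
        response_side=response_side,
        target=target,
        opposite=opposite,
        w0=tp.w_base + tp.attraction_gain * params.bias * incong,
        tau_eff=tp.tau * (1.0 + tp.conflict_persistence * params.bias * incong),
        speed_scale=1.0 / (1.0 + tp.conflict_slowdown * params.bias * incong),
    )
    source = (r, n, tp.heading_noise_sd)
    return arrays, source


def _extend_noise(noise, sources, keeps):
    """Append the next heading-noise block from each session's stream.

    ``keeps[i]`` selects which rows of source ``i``'s full block survive in
    the stacked ``noise`` array (all rows for a session, one row when a
    single trial is re-simulated), keeping stream consumption identical
    across batched and isolated runs.
    """
    blocks = []
    for (r, n_rows, sd), keep in zip(sources, keeps):
        block = r.standard_normal((n_rows, NOISE_CHUNK_STEPS)) * sd
        blocks.append(block[keep])
    return np.concatenate([noise, np.vstack(blocks)], axis=1)


def _integrate_trials(arrays, design, tp, sources, keeps):
    """Per-step cursor dynamics for a stack of independent trials.

    Dynamics are elementwise per trial, so batching any number of trials
    (within or across subjects) produces bitwise-identical paths.
    Returns ``(path, n_move)``: positions after each movement step and the
    number of steps each trial needed.
    """
    dt = design.sample_interval
    max_steps = int(round(tp.max_duration / dt))
    target = arrays["target"]
    opposite = arrays["opposite"]
    w0 = arrays["w0"]
    tau_eff = arrays["tau_eff"]
    speed_scale = arrays["speed_scale"]
    noise = arrays["noise"]
    n = len(target)

    start = np.array(design.start_pos, float)
    pos = np.tile(start, (n, 1))
    cap = 256  # grow the position buffer on demand; most trials finish early
    path = np.empty((n, cap, 2), float)
    active = np.ones(n, bool)
    n_move = np.zeros(n, int)
    k = 0
    while active.any():
        if k >= max_steps:
            raise GenerationError(
                f"{int(active.sum())} trajectories did not reach the response box "
                f"within {tp.max_duration:.0f} ms"
            )
        if k >= path.shape[1]:
            path = np.concatenate([path, np.empty((n, cap, 2), float)], axis=1)
        if k >= noise.shape[1]:
            noise = _extend_noise(noise, sources, keeps)
        idx = np.nonzero(active)[0]
        p = pos[idx]
        t_m = k * dt
        to_t = target[idx] - p
        d_t = np.hypot(to_t[:, 0], to_t[:, 1])
        u_t = to_t / np.maximum(d_t, 1e-9)[:, None]
        to_o = opposite[idx] - p
        d_o = np.hypot(to_o[:, 0], to_o[:, 1])
        u_o = to_o / np.maximum(d_o, 1e-9)[:, None]
        w = w0[idx] * np.exp(-t_m / tau_eff[idx])
        head = (1.0 - w)[:, None] * u_t + w[:, None] * u_o
        head /= np.maximum(np.hypot(head[:, 0], head[:, 1]), 1e-9)[:, None]
        th = noise[idx, k]
        c, s = np.cos(th), np.sin(th)
        hx = c * head[:, 0] - s * head[:, 1]
        hy = s * head[:, 0] + c * head[:, 1]
        # conflict slows the movement by dilating the whole speed profile in
        # time: v(t) = s * profile(s * t) integrates to the same path length
        # over a 1/s-times longer movement
        ts = t_m * speed_scale[idx]
        v = (
            tp.v_base + tp.v_peak * np.exp(-0.5 * ((ts - tp.v_peak_time) / tp.v_width) ** 2)
        ) * speed_scale[idx]
        p = p + (v * dt)[:, None] * np.column_stack([hx, hy])
        pos[idx] = p
        path[idx, k] = p
        d_end = target[idx] - p
        arrived = np.hypot(d_end[:, 0], d_end[:, 1]) <= design.box_radius
        done = idx[arrived]
        n_move[done] = k + 1
        active[done] = False
        k += 1
    return path, n_move


def _assemble_session(subject_id, schedule, arrays, path, n_move, design):
    """Raw trajectories plus the trial-outcome table for one session."""
    dt = design.sample_interval
    start = np.array(design.start_pos, float)
    it = arrays["it"]
    n_pre = np.maximum(np.rint(it / dt).astype(int), 1)
    totals = n_pre + n_move
    master_t = np.arange(totals.max()) * dt
    blocks = schedule["block"].to_numpy()
    trial_ids = schedule["trial"].to_numpy()
    trajectories: list[RawTrajectory] = []
    # samples 0 .. n_pre-1 sit at the start button; sample n_pre + j is the
    # position after movement step j
    for i in range(len(schedule)):
        total = totals[i]
        x = np.full(total, start[0])
        y = np.full(total, start[1])
        x[n_pre[i] :] = path[i, : n_move[i], 0]
        y[n_pre[i] :] = path[i, : n_move[i], 1]
        trajectories.append(
            RawTrajectory._unchecked(
                subject=subject_id,
                block=int(blocks[i]),
                trial=int(trial_ids[i]),
                t=master_t[:total].copy(),
                x=x,
                y=y,
            )
        )
    meta = schedule[
        ["block", "trial", "practice", "stimulus", "condition", "congruency", "correct_side"]
    ].copy()
    meta.insert(0, "subject", subject_id)
    meta["response"] = arrays["response_side"]
    meta["correct"] = arrays["chosen_correct"]
    meta["rt_ms"] = (totals - 1) * dt
    return trajectories, meta.reset_index(drop=True)


def simulate_mouse_session(
    params: SubjectParams,
    schedule: pd.DataFrame,
    design: DesignConfig,
    seed: int,
    traj_params: TrajectoryParams | None = None,
    subject_index: int = 0,
) -> tuple[list[RawTrajectory], pd.DataFrame]:
    """Simulate one mouse session: trajectories plus a trial-outcome table."""
    tp = traj_params or TrajectoryParams()
    arrays, source = _mouse_trial_arrays(params, schedule, design, tp, seed, subject_index)
    keep = np.arange(len(schedule))
    path, n_move = _integrate_trials(arrays, design, tp, [source], [keep])
    return _assemble_session(params.subject_id, schedule, arrays, path, n_move, design)


def simulate_mouse_trial(
    spec: pd.Series,
    params: SubjectParams,
    design: DesignConfig,
    seed: int,
    traj_params: TrajectoryParams | None = None,
    subject_index: int = 0,
    trial_counter: int | None = None,
) -> tuple[RawTrajectory, pd.Series]:
    """Simulate a single mouse trial (identical to its in-session result).

    The subject's session schedule is rebuilt from ``seed`` and the trial
    at ``trial_counter`` (default: the schedule row matching ``spec``) is
    regenerated in isolation.
    """
    tp = traj_params or TrajectoryParams()
    schedule = build_schedule(design, seed, task="mouse", subject_index=subject_index)
    if trial_counter is None:
        match = schedule[
            (schedule["block"] == spec["block"]) & (schedule["trial"] == spec["trial"])
        ]
        if len(match) != 1:
            raise ValueError("spec does not identify a unique schedule row")
        trial_counter = int(match.index[0])
    arrays, source = _mouse_trial_arrays(params, schedule, design, tp, seed, subject_index)
    arrays = {k: v[trial_counter : trial_counter + 1] for k, v in arrays.items()}
    row_spec = schedule.iloc[trial_counter : trial_counter + 1]
    keep = np.array([trial_counter])
    path, n_move = _integrate_trials(arrays, design, tp, [source], [keep])
    trajs, meta = _assemble_session(params.subject_id, row_spec, arrays, path, n_move, design)
    return trajs[0], meta.iloc[0]


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SessionSet:
    """A simulated cohort: shared subject parameters, both task variants."""

    subjects: pd.DataFrame
    keyboard: pd.DataFrame
    mouse_meta: pd.DataFrame
    trajectories: list[RawTrajectory]
    design: DesignConfig
    population: PopulationConfig
    traj_params: TrajectoryParams
    seed: int

    def to_dir(self, path: str | Path) -> Path:
        """Write the cohort in the package's standard file formats."""
        from . import io as mio

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        mio.write_trial_table(self.keyboard, out / "keyboard.csv")
        mio.write_trial_table(self.mouse_meta, out / "mouse_trials.csv")
        mio.write_trajectory_log(self.trajectories, out / "trajectories.csv")
        mio.write_config(
            {
                **{f"design.{k}": v for k, v in asdict(self.design).items()},
                **{f"population.{k}": v for k, v in asdict(self.population).items()},
                **{f"trajectory.{k}": v for k, v in asdict(self.traj_params).items()},
                "seed": self.seed,
            },
            out / "config.yaml",
        )
        return out


def simulate_cohort(
    n_subjects: int,
    seed: int,
    design: DesignConfig | None = None,
    population: PopulationConfig | None = None,
    traj_params: TrajectoryParams | None = None,
    out_dir: str | Path | None = None,
) -> SessionSet:
    """Simulate ``n_subjects`` paired keyboard + mouse sessions.

    Each subject's latent bias is drawn once and used in both tasks, so the
    association between keyboard D scores and mouse congruency effects is
    recoverable by the downstream pipeline.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    design = design or DesignConfig()
    population = population or PopulationConfig()
    tp = traj_params or TrajectoryParams()

    subj_rows = []
    kb_frames = []
    mouse_frames = []
    trajectories: list[RawTrajectory] = []
    # the per-trial dynamics are independent, so mouse sessions are
    # integrated in multi-subject batches (identical results, fewer
    # python-level steps); chunking bounds the noise/path buffers
    chunk: list[tuple] = []

    def flush():
        if not chunk:
            return
        merged = {
            key: np.concatenate([a[key] for _, _, a, _ in chunk])
            for key in chunk[0][2]
        }
        sources = [src for _, _, _, src in chunk]
        keeps = [np.arange(len(sched)) for _, sched, _, _ in chunk]
        path, n_move = _integrate_trials(merged, design, tp, sources, keeps)
        offset = 0
        for sid, sched, arrays, _ in chunk:
            n = len(sched)
            sl = slice(offset, offset + n)
            trajs, meta = _assemble_session(sid, sched, arrays, path[sl], n_move[sl], design)
            mouse_frames.append(meta)
            trajectories.extend(trajs)
            offset += n
        chunk.clear()

    for i in range(n_subjects):
        kb_params, mouse_params = draw_subject_params(population, seed, i)
        kb_sched = build_schedule(design, seed, task="keyboard", subject_index=i)
        kb_frames.append(simulate_keyboard_session(kb_params, kb_sched, seed, i))
        mouse_sched = build_schedule(design, seed, task="mouse", subject_index=i)
        arrays, source = _mouse_trial_arrays(mouse_params, mouse_sched, design, tp, seed, i)
        chunk.append((mouse_params.subject_id, mouse_sched, arrays, source))
        if len(chunk) >= 16:
            flush()
        subj_rows.append(
            dict(
                subject=kb_params.subject_id,
                bias=kb_params.bias,
                base_log_rt=kb_params.base_log_rt,
                base_it=kb_params.base_it,
                error_rate_congruent=kb_params.error_rate_congruent,
                error_rate_incongruent=kb_params.error_rate_incongruent,
            )
        )
    flush()
    sessions = SessionSet(
        subjects=pd.DataFrame(subj_rows),
        keyboard=pd.concat(kb_frames, ignore_index=True),
        mouse_meta=pd.concat(mouse_frames, ignore_index=True),
        trajectories=trajectories,
        design=design,
        population=population,
        traj_params=tp,
        seed=seed,
    )
    if out_dir is not None:
        sessions.to_dir(out_dir)
    return sessions
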