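"""Generator behaviour: effect directions, determinism, sampling grid."""

import numpy as np
import pandas as pd
import pytest

from mtiat import (
    GenerationError,
    build_schedule,
    simulate_cohort,
    simulate_keyboard_session,
    simulate_mouse_session,
    simulate_mouse_trial,
)
from mtiat.metrics import max_deviation
from mtiat.preprocess import preprocess_batch
from mtiat.simulate import PopulationConfig, SubjectParams, TrajectoryParams


def make_params(bias, **kw):
    base = dict(
        subject_id="S0",
        bias=bias,
        base_log_rt=np.log(700),
        rt_sd=0.22,
        base_it=240.0,
        it_sd=45.0,
        error_rate_congruent=0.04,
        error_rate_incongruent=0.10,
    )
    base.update(kw)
    return SubjectParams(**base)


@pytest.fixture(scope="module")
def sched(design):
    return build_schedule(design, seed=0, task="keyboard")


class TestKeyboard:
    def test_null_bias_symmetry(self, design, sched):
        rts = []
        for s in range(30):
            t = simulate_keyboard_session(make_params(0.0), sched, seed=s)
            rts.append(
                t.groupby("congruency")["rt_ms"].mean().loc[["incongruent", "congruent"]]
            )
        diff = np.mean([r.iloc[0] - r.iloc[1] for r in rts])
        # Monte-Carlo error of the mean difference at ~2400 trials per cell
        assert abs(diff) < 15.0

    def test_positive_bias_slows_incongruent(self, sched):
        t = simulate_keyboard_session(make_params(0.3), sched, seed=1)
        means = t.groupby("congruency")["rt_ms"].mean()
        assert means["incongruent"] > means["congruent"]

    def test_deterministic(self, sched):
        a = simulate_keyboard_session(make_params(0.2), sched, seed=9)
        b = simulate_keyboard_session(make_params(0.2), sched, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestMouse:
    def test_sampling_grid_is_100hz(self, design, sched):
        trajs, _ = simulate_mouse_session(make_params(0.3), sched.head(10), design, seed=2)
        for tr in trajs:
            assert np.allclose(np.diff(tr.t), 10.0)
            assert tr.t[0] == 0.0

    def test_no_attraction_no_noise_is_straight(self, design, sched):
        tp = TrajectoryParams(w_base=0.0, attraction_gain=0.0, heading_noise_sd=0.0)
        trajs, meta = simulate_mouse_session(
            make_params(0.0, error_rate_congruent=0.0, error_rate_incongruent=0.0),
            sched.head(8),
            design,
            seed=3,
            traj_params=tp,
        )
        batch = preprocess_batch(trajs, design)
        md, _, _ = max_deviation(batch)
        assert np.all(np.abs(md) < 5.0 / 688.0)  # within half a box radius

    def test_attraction_bias_raises_incongruent_md(self, design):
        sched = build_schedule(design, seed=5, task="keyboard")
        crit = sched[sched.block.isin([3, 4, 6, 7])].reset_index(drop=True)
        trajs, meta = simulate_mouse_session(make_params(0.4), crit, design, seed=5)
        batch = preprocess_batch(trajs, design)
        md, _, _ = max_deviation(batch)
        frame = batch.keys.copy()
        frame["md"] = md
        frame = frame.merge(
            crit.assign(trial_key=np.arange(len(crit))), left_index=True, right_index=True
        )
        means = frame.groupby("congruency")["md"].mean()
        assert means["incongruent"] > means["congruent"]

    def test_trial_matches_session(self, design):
        params = make_params(0.25)
        mouse_sched = build_schedule(design, seed=7, task="mouse")
        trajs, meta = simulate_mouse_session(params, mouse_sched, design, seed=7)
        for k in (0, 57, 130):
            tr, row = simulate_mouse_trial(mouse_sched.iloc[k], params, design, seed=7)
            assert np.array_equal(tr.x, trajs[k].x)
            assert np.array_equal(tr.t, trajs[k].t)
            assert row["rt_ms"] == meta.iloc[k]["rt_ms"]

    def test_nonterminating_trajectory_raises(self, design, sched):
        tp = TrajectoryParams(v_base=0.0, v_peak=0.0001, max_duration=500.0)
        with pytest.raises(GenerationError):
            simulate_mouse_session(make_params(0.2), sched.head(2), design, seed=8, traj_params=tp)


class TestCohort:
    def test_single_subject_identity(self):
        ss = simulate_cohort(1, seed=4)
        assert ss.keyboard.subject.nunique() == 1
        assert ss.mouse_meta.subject.nunique() == 1
        assert ss.keyboard.subject.iloc[0] == ss.mouse_meta.subject.iloc[0]

    def test_deterministic_byte_identical(self, tmp_path):
        a = simulate_cohort(2, seed=21, out_dir=tmp_path / "a")
        simulate_cohort(2, seed=21, out_dir=tmp_path / "b")
        for name in ("keyboard.csv", "mouse_trials.csv", "trajectories.csv", "subjects.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_zero_bias_population_null_d(self, small_cohort):
        from mtiat.dscore import score_subjects

        pop = PopulationConfig(bias_mean=0.0, bias_sd=0.0)
        ds = []
        for s in range(8):
            ss = simulate_cohort(4, seed=200 + s, population=pop)
            ds.extend(score_subjects(ss.keyboard)["d"].tolist())
        mean = np.mean(ds)
        assert abs(mean) < 3 * np.std(ds) / np.sqrt(len(ds)) + 0.08
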