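"""Trajectory metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from mtiat.metrics import (
    DegenerateTrajectoryError,
    area_under_curve,
    compute_metric_set,
    max_deviation,
    sample_entropy,
    x_dynamics,
    x_flips,
)
from mtiat.preprocess import preprocess_batch
from mtiat.metrics import compute_metrics

from conftest import random_batch, single_trajectory


def brute_md(x, y):
    """Max |point-to-chord distance| by explicit loop."""
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    ex, ey = x1 - x0, y1 - y0
    norm = np.hypot(ex, ey)
    best, best_i = 0.0, 0
    for i in range(len(x)):
        d = (ex * (y[i] - y0) - ey * (x[i] - x0)) / norm
        if abs(d) > abs(best):
            best, best_i = d, i
    return best, best_i


def brute_auc(x, y, per_seg=200):
    """Signed area by dense integration in the chord-aligned frame."""
    x0, y0 = x[0], y[0]
    ex, ey = x[-1] - x0, y[-1] - y0
    norm = np.hypot(ex, ey)
    ux, uy = ex / norm, ey / norm
    # rotate so the chord is the u axis; v is the signed offset (left > 0)
    u = (x - x0) * ux + (y - y0) * uy
    v = -(x - x0) * uy + (y - y0) * ux
    total = 0.0
    for i in range(len(x) - 1):
        uu = np.linspace(u[i], u[i + 1], per_seg)
        vv = np.linspace(v[i], v[i + 1], per_seg)
        total += np.trapezoid(vv, uu)
    return total


class TestMaxDeviation:
    def test_straight_path_zero(self):
        t = np.linspace(0, 1, 101)
        tr = single_trajectory(0.7 * t, t)
        md, step, md_time = max_deviation(tr)
        assert md == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_detour_closed_form(self):
        # path rises along x=0 then crosses to (1,1); apex distance sqrt(2)/2
        x = np.concatenate([np.zeros(51), np.linspace(0, 1, 50)])
        y = np.concatenate([np.linspace(0, 1, 51), np.ones(50)])
        tr = single_trajectory(x, y)
        md, step, _ = max_deviation(tr)
        assert abs(md) == pytest.approx(np.sqrt(2) / 2, abs=1e-9)
        assert step == 50
        assert md > 0  # left of the chord = positive sign

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        batch = random_batch(rng, 200)
        md, step, _ = max_deviation(batch)
        for i in range(len(batch)):
            b, bi = brute_md(batch.x[i], batch.y[i])
            assert md[i] == pytest.approx(b, abs=1e-12)
            assert step[i] == bi

    def test_degenerate_rejected(self):
        x = np.zeros(101)
        with pytest.raises(DegenerateTrajectoryError):
            max_deviation(single_trajectory(x, x))


class TestAUC:
    def test_straight_path_zero(self):
        t = np.linspace(0, 1, 101)
        assert area_under_curve(single_trajectory(0.6 * t, t)) == pytest.approx(0, abs=1e-12)

    def test_triangle_half(self):
        x = np.concatenate([np.zeros(51), np.linspace(0, 1, 50)])
        y = np.concatenate([np.linspace(0, 1, 51), np.ones(50)])
        auc = area_under_curve(single_trajectory(x, y))
        assert auc == pytest.approx(0.5, abs=1e-9)  # left detour -> positive

    def test_overshoot_side_negative(self):
        x = np.concatenate([np.linspace(0, 1, 51), np.ones(50)])
        y = np.concatenate([np.zeros(51), np.linspace(0, 1, 50)])
        assert area_under_curve(single_trajectory(x, y)) == pytest.approx(-0.5, abs=1e-9)

    def test_matches_dense_integration(self):
        rng = np.random.default_rng(7)
        batch = random_batch(rng, 50)
        auc = area_under_curve(batch)
        for i in range(len(batch)):
            assert auc[i] == pytest.approx(brute_auc(batch.x[i], batch.y[i]), abs=1e-6)


class TestDynamics:
    def test_constant_ramp_first_occurrence(self):
        x = np.arange(101, dtype=float)  # exactly equal steps
        tr = single_trajectory(x, x, rt=1000.0)
        vel_max, vel_max_t, acc_max, acc_max_t = x_dynamics(tr)
        assert vel_max == pytest.approx(1.0)
        assert vel_max_t == 0.0  # all velocities tie; first step wins
        assert acc_max == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_ramp(self):
        steps = np.arange(101, dtype=float)
        tr = single_trajectory(steps**2, steps, rt=1000.0)
        vel_max, vel_max_t, acc_max, acc_max_t = x_dynamics(tr)
        v = np.diff(steps**2)
        assert vel_max == v.max()
        assert vel_max_t == pytest.approx(99 * 10.0)  # last velocity index
        assert acc_max == pytest.approx(2.0)
        assert acc_max_t == 0.0


class TestFlips:
    @pytest.mark.parametrize(
        "xs,expected",
        [
            (np.linspace(0, 1, 101), 0),
            ([0, 1, 0, 1, 0], 3),
            ([0, 1, 1, 0], 1),  # interior zero step skipped
            ([0, 0, 0, 1], 0),
        ],
    )
    def test_flip_counts(self, xs, expected):
        xs = np.asarray(xs, float)
        tr = single_trajectory(xs, np.linspace(0, 1, len(xs)))
        assert x_flips(tr) == expected


class TestSampleEntropy:
    def test_constant_series_undefined(self):
        tr = single_trajectory(np.ones(101), np.linspace(0, 1, 101))
        ent, ok = sample_entropy(tr)
        assert not ok and np.isnan(ent)

    def test_alternating_series_zero(self):
        x = np.cumsum(np.tile([1.0, -1.0], 50))[:101]
        x = np.concatenate([[0], np.cumsum(np.tile([1.0, -1.0], 50))])
        tr = single_trajectory(x, np.linspace(0, 1, 101))
        ent, ok = sample_entropy(tr)
        assert ok
        assert ent == pytest.approx(0.0, abs=1e-12)

    def test_matches_template_counting_oracle(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=101))
        tr = single_trajectory(x, np.linspace(0, 1, 101))
        ent, ok = sample_entropy(tr, m=3, r_frac=0.2)
        series = np.diff(x)
        r = 0.2 * series.std()
        n, m = len(series), 3
        a = b = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(series[i + k] - series[j + k]) for k in range(m)) <= r:
                    b += 1
                    if abs(series[i + m] - series[j + m]) <= r:
                        a += 1
        assert ok
        assert ent == pytest.approx(-np.log(a / b), abs=1e-12)


class TestProperties:
    def test_mirror_negates_md_and_auc(self):
        rng = np.random.default_rng(11)
        batch = random_batch(rng, 30)
        md, _, _ = max_deviation(batch)
        auc = area_under_curve(batch)
        mirrored = random_batch(rng, 30)
        # reflect each path about its own chord
        for i in range(len(batch)):
            x, y = batch.x[i], batch.y[i]
            x0, y0 = x[0], y[0]
            ex, ey = x[-1] - x0, y[-1] - y0
            nn = ex * ex + ey * ey
            u = ((x - x0) * ex + (y - y0) * ey) / nn
            v = ((x - x0) * -ey + (y - y0) * ex) / nn
            mirrored.x[i] = x0 + u * ex - (-v) * -ey * 1  # rebuild with v -> -v
            mirrored.x[i] = x0 + u * ex + (-v) * -ey
            mirrored.y[i] = y0 + u * ey + (-v) * ex
        md2, _, _ = max_deviation(mirrored)
        auc2 = area_under_curve(mirrored)
        np.testing.assert_allclose(md2, -md, atol=1e-9)
        np.testing.assert_allclose(auc2, -auc, atol=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(12)
        batch = random_batch(rng, 20)
        md, _, _ = max_deviation(batch)
        auc = area_under_curve(batch)
        c = 2.5
        scaled = random_batch(rng, 20)
        scaled.x[:] = c * batch.x
        scaled.y[:] = c * batch.y
        md2, _, _ = max_deviation(scaled)
        np.testing.assert_allclose(md2, c * md, rtol=1e-12)
        np.testing.assert_allclose(area_under_curve(scaled), c * c * auc, rtol=1e-12)

    def test_time_ordering_on_simulated_trials(self, design, small_cohort):
        trajs = [t for t in small_cohort.trajectories if t.block in (3, 4, 6, 7)]
        batch = preprocess_batch(trajs, design)
        table = compute_metrics(batch, entropy=False)
        assert (table.it_ms >= 0).all()
        assert (table.md_time_ms <= table.rt_ms).all()
        assert (table.md_time_ms >= table.it_ms).mean() > 0.99

    def test_metric_set_consistent_with_table(self, design, small_cohort):
        trajs = [t for t in small_cohort.trajectories if t.block in (3, 4, 6, 7)][:5]
        batch = preprocess_batch(trajs, design)
        table = compute_metrics(batch, entropy=True)
        ms = compute_metric_set(batch.to_list()[2])
        row = table.iloc[2]
        assert ms.md == pytest.approx(row.md)
        assert ms.auc == pytest.approx(row.auc)
        assert ms.entropy == pytest.approx(row.entropy, nan_ok=True)
        assert ms.xpos_flips == row.xpos_flips
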