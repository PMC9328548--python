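"""Inference helpers: closed forms, antisymmetries, an exact Wilcoxon oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mtiat.stats import (
    cell_means,
    delta_scores,
    interaction_contrast,
    ols_association,
    one_sample_t,
    paired_wilcoxon,
    phase_contrasts,
    tucker_phi,
)


class TestDeltaScores:
    @staticmethod
    def table(values):
        rows = []
        for subj, cond, vals in values:
            for v in vals:
                rows.append(dict(subject=subj, congruency=cond, md=v))
        return pd.DataFrame(rows)

    def test_zero_when_identical(self):
        t = self.table([("a", "congruent", [1, 2]), ("a", "incongruent", [1, 2])])
        assert delta_scores(t, "md").delta_md.iloc[0] == 0

    def test_arithmetic(self):
        t = self.table([("a", "congruent", [0.6]), ("a", "incongruent", [0.9])])
        assert delta_scores(t, "md").delta_md.iloc[0] == pytest.approx(0.3)

    def test_subject_missing_condition_excluded(self):
        t = self.table([("a", "congruent", [1]), ("a", "incongruent", [2]),
                        ("b", "congruent", [1])])
        out = delta_scores(t, "md")
        assert out.subject.tolist() == ["a"]

    def test_shift_linearity(self):
        t = self.table([("a", "congruent", [0.5, 0.7]), ("a", "incongruent", [0.8, 1.0])])
        base = delta_scores(t, "md").delta_md.iloc[0]
        t2 = t.copy()
        t2.loc[t2.congruency == "incongruent", "md"] += 0.25
        assert delta_scores(t2, "md").delta_md.iloc[0] == pytest.approx(base + 0.25)

    def test_positive_on_biased_cohort(self, small_fit):
        assert small_fit.delta_md.delta_md.mean() > 0


class TestInteractionContrast:
    @staticmethod
    def cells(rows):
        frame = pd.DataFrame(
            rows, columns=["White-Positive", "White-Negative", "Black-Positive", "Black-Negative"]
        )
        frame.index.name = "subject"
        return frame

    def test_all_equal_zero(self):
        c = self.cells([[1.0, 1, 1, 1], [2.0, 2, 2, 2], [2.0, 2, 2, 2.1]])
        frame, test = interaction_contrast(c)
        assert frame.contrast.iloc[0] == 0

    def test_maximal_pattern(self):
        c = self.cells([[0.0, 1.0, 1.0, 0.0]] * 3)
        frame, _ = interaction_contrast(c)
        assert (frame.contrast == 2.0).all()

    def test_significant_on_biased_cohort(self, small_fit):
        assert small_fit.interaction_md["t"] > 0
        assert small_fit.interaction_md["p"] < 0.05


class TestOneSampleT:
    def test_mean_equals_mu0(self):
        t, df, p = one_sample_t(np.array([1.0, 2.0, 3.0]), mu0=2.0)
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        t, df, p = one_sample_t(np.array([1.0, 2, 3, 4, 5]))
        assert t == pytest.approx(3 / (np.sqrt(2.5) / np.sqrt(5)), abs=1e-10)
        assert t == pytest.approx(4.242640687, abs=1e-8)
        assert df == 4

    def test_antisymmetry(self):
        x = np.array([0.3, 1.2, -0.5, 2.0])
        t1, _, p1 = one_sample_t(x)
        t2, _, p2 = one_sample_t(-x)
        assert t2 == -t1 and p1 == p2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(np.ones(4))


def wilcoxon_exact_p(diff):
    """Exact two-sided signed-rank p by enumeration over sign patterns."""
    diff = np.asarray(diff, float)
    n = len(diff)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_obs = ranks[diff > 0].sum()
    mu = n * (n + 1) / 4
    count = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_rejected(self):
        x = np.arange(6, dtype=float)
        with pytest.raises(ValueError):
            paired_wilcoxon(x, x)

    def test_shifted_sample_direction_and_exact_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        y = x + 1.0
        w, r, p = paired_wilcoxon(x, y)
        assert r < 0  # x systematically below y
        exact = wilcoxon_exact_p(x - y)
        # normal approximation tracks the exact enumeration at small n
        assert p == pytest.approx(exact, abs=0.04)

    def test_random_pairs_match_exact_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=9)
            y = x + rng.normal(0.6, 1.0, size=9)
            if np.any(x == y):
                continue
            _, _, p = paired_wilcoxon(x, y)
            assert p == pytest.approx(wilcoxon_exact_p(x - y), abs=0.05)

    def test_swap_negates_effect_size(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = x + rng.normal(0.5, 0.8, size=12)
        _, r1, p1 = paired_wilcoxon(x, y)
        _, r2, p2 = paired_wilcoxon(y, x)
        assert r2 == pytest.approx(-r1)
        assert p1 == pytest.approx(p2)


class TestOLS:
    def test_exact_fit(self):
        d = np.array([0.1, 0.5, 0.9, 1.3])
        res = ols_association(d, 2 * d)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2

    def test_closed_form_slope(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        res = ols_association(x, y)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slope == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_association(np.ones(5), np.arange(5.0))


class TestTuckerPhi:
    def test_identical_vectors(self):
        v = np.array([0.7, 0.2, 0.5])
        assert tucker_phi(v, v).phi[0] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert tucker_phi([1.0, 0.0], [0.0, 1.0]).phi[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        res = tucker_phi([0.9, 0.1], [0.1, 0.9])
        assert res.phi[0] == pytest.approx(0.18 / 0.82, abs=1e-12)

    def test_scaling_invariance(self):
        a = np.array([0.8, -0.3, 0.1])
        b = np.array([0.6, 0.4, -0.2])
        assert tucker_phi(3.7 * a, b).phi[0] == pytest.approx(tucker_phi(a, b).phi[0])

    def test_matrix_columns(self):
        A = np.array([[0.9, 0.0], [0.1, 0.9], [0.0, 0.4]])
        res = tucker_phi(A, A)
        np.testing.assert_allclose(res.phi, [1.0, 1.0])

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            tucker_phi([0.0, 0.0], [1.0, 0.0])


class TestPhaseContrasts:
    @staticmethod
    def table(early, mid, late):
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(len(early))],
                "early_index_ms": early,
                "mid_index_ms": mid,
                "late_index_ms": late,
            }
        )

    def test_equal_indices_all_p_one(self):
        t = self.table([10.0] * 5, [10.0] * 5, [10.0] * 5)
        out = phase_contrasts(t)
        assert (out.p == 1.0).all() and (out.p_holm == 1.0).all()

    def test_mid_dominant_pattern(self, small_fit):
        out = small_fit.phase_comparison.set_index("pair")
        assert out.loc["early-mid", "mean_diff_ms"] < 0
        assert out.loc["mid-late", "mean_diff_ms"] > 0

    def test_label_permutation_null_calibration(self):
        """Uniformly permuting phase labels within subjects is a true null;
        the Holm-corrected family-wise rejection rate stays below alpha."""
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 200
        for _ in range(reps):
            vals = rng.normal(50, 20, size=(12, 3))
            for row in vals:
                rng.shuffle(row)
            out = phase_contrasts(self.table(vals[:, 0], vals[:, 1], vals[:, 2]))
            rejections += (out.p_holm < 0.05).any()
        assert rejections / reps < 0.09


def test_cell_means_shape(small_fit):
    cells = cell_means(small_fit.metrics, "md")
    assert list(cells.columns) == [
        "White-Positive", "White-Negative", "Black-Positive", "Black-Negative"
    ]
    assert cells.notna().all().all()
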