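"""Model/Results facade over the full race-IAT analysis chain.

``RaceIAT`` is built from a cohort's keyboard trial table, mouse trial
table and raw trajectories (or directly from a simulated
:class:`~mtiat.simulate.SessionSet`); ``fit()`` runs preprocessing,
exclusion, metric extraction, D scoring, the congruency contrasts, the
distributional (dip) analysis and the phase decomposition, and returns a
:class:`RaceIATResults` carrying every table plus a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distribution, dscore, metrics as mmetrics, phases as mphases, stats as mstats
from .design import CRITICAL_BLOCKS, DesignConfig
from .preprocess import ExclusionReport, critical_records, filter_trials, preprocess_batch
from .simulate import SessionSet
from .trajectory import RawTrajectory


class RaceIAT:
    """Joint keyboard + mouse-tracking race-IAT analysis of one cohort."""

    def __init__(
        self,
        keyboard_trials: pd.DataFrame,
        mouse_trials: pd.DataFrame,
        trajectories: list[RawTrajectory],
        design: DesignConfig | None = None,
    ) -> None:
        self.keyboard_trials = keyboard_trials
        self.mouse_trials = mouse_trials
        self.trajectories = trajectories
        self.design = design or DesignConfig()

    @classmethod
    def from_session_set(cls, sessions: SessionSet) -> "RaceIAT":
        return cls(
            keyboard_trials=sessions.keyboard,
            mouse_trials=sessions.mouse_meta,
            trajectories=sessions.trajectories,
            design=sessions.design,
        )

    @classmethod
    def from_dir(cls, path: str | Path, design: DesignConfig | None = None) -> "RaceIAT":
        from . import io as mio

        path = Path(path)
        return cls(
            keyboard_trials=mio.read_trial_table(path / "keyboard.csv"),
            mouse_trials=mio.read_trial_table(path / "mouse_trials.csv"),
            trajectories=mio.read_trajectory_log(path / "trajectories.csv"),
            design=design,
        )

    def fit(
        self,
        n_boot: int = 2000,
        seed: int = 0,
        sd_scope: str = "subject",
        entropy: bool = True,
    ) -> "RaceIATResults":
        """Run the full analysis chain.

        ``n_boot``/``seed`` control the dip test's Monte-Carlo null;
        ``sd_scope`` selects per-subject or pooled reaction-time outlier
        screening; ``entropy=False`` skips the sample-entropy column.
        """
        # --- keyboard: D scores
        d_scores = dscore.score_subjects(self.keyboard_trials)

        # --- mouse: preprocess critical-block trajectories
        crit_trajs = [tr for tr in self.trajectories if tr.block in CRITICAL_BLOCKS]
        if not crit_trajs:
            raise ValueError("no critical-block trajectories")
        batch = preprocess_batch(crit_trajs, self.design)
        records = critical_records(self.mouse_trials, batch)
        kept, exclusions = filter_trials(records, sd_scope=sd_scope)

        mask = (
            batch.keys.merge(
                kept[["subject", "block", "trial"]].assign(_kept=True),
                on=["subject", "block", "trial"],
                how="left",
            )["_kept"]
            .notna()
            .to_numpy(dtype=bool)
        )
        from .trajectory import NormalizedBatch

        kept_batch = NormalizedBatch(
            keys=batch.keys[mask].reset_index(drop=True),
            x=batch.x[mask],
            y=batch.y[mask],
            step_times=batch.step_times[mask],
            initiation_time=batch.initiation_time[mask],
            response_time=batch.response_time[mask],
            remapped=batch.remapped[mask],
        )
        metric_table = mmetrics.compute_metrics(kept_batch, entropy=entropy)
        metric_table = metric_table.merge(
            kept[["subject", "block", "trial", "condition", "congruency"]],
            on=["subject", "block", "trial"],
        )

        # --- congruency effects
        delta_md = mstats.delta_scores(metric_table, "md")
        delta_amt = mstats.delta_scores(metric_table, "acc_max_time_ms")
        cells_md = mstats.cell_means(metric_table, "md")
        contrast_md, test_md = mstats.interaction_contrast(cells_md)
        cells_amt = mstats.cell_means(metric_table, "acc_max_time_ms")
        contrast_amt, test_amt = mstats.interaction_contrast(cells_amt)

        # --- distributional analysis of z-transformed MD
        rng = np.random.default_rng(seed)
        dip_results = {}
        for cond in ("congruent", "incongruent"):
            vals = metric_table.loc[metric_table["congruency"] == cond, "md"].to_numpy()
            z = distribution.zscore(vals)
            dip_results[cond] = distribution.dip_test(
                z, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
            )

        # --- phase decomposition
        phase_tab = mphases.phase_table(metric_table, on_missing="drop")
        early_test = mstats.one_sample_t(phase_tab["early_index_ms"].to_numpy())
        phase_cmp = mstats.phase_contrasts(phase_tab)

        # --- associations with the D score
        assoc = {}
        d_map = d_scores.set_index("subject")["d"]
        for name, frame, col in (
            ("delta_md", delta_md, "delta_md"),
            ("delta_acc_max_time", delta_amt, "delta_acc_max_time_ms"),
            ("early_index", phase_tab, "early_index_ms"),
            ("mid_index", phase_tab, "mid_index_ms"),
            ("late_index", phase_tab, "late_index_ms"),
        ):
            merged = frame.merge(d_map.rename("d"), left_on="subject", right_index=True)
            if len(merged) >= 3 and merged["d"].std(ddof=1) > 0:
                assoc[name] = mstats.ols_association(
                    merged["d"].to_numpy(), merged[col].to_numpy()
                )

        # --- keyboard vs mouse task comparison (accuracy and RT)
        task_cmp = self._task_comparison()

        return RaceIATResults(
            model=self,
            d_scores=d_scores,
            exclusions=exclusions,
            metrics=metric_table,
            delta_md=delta_md,
            delta_acc_max_time=delta_amt,
            interaction_md=test_md,
            interaction_acc_max_time=test_amt,
            contrast_md=contrast_md,
            contrast_acc_max_time=contrast_amt,
            dip=dip_results,
            phase_table=phase_tab,
            early_phase_test=dict(
                zip(("t", "df", "p"), early_test)
            ),
            phase_comparison=phase_cmp,
            associations=assoc,
            task_comparison=task_cmp,
        )

    def _task_comparison(self) -> pd.DataFrame:
        """Wilcoxon comparisons of accuracy and RT between the two tasks."""
        kb = self.keyboard_trials
        mt = self.mouse_trials[~self.mouse_trials["practice"].astype(bool)] if "practice" in self.mouse_trials else self.mouse_trials
        kb_crit = kb[kb["block"].isin(CRITICAL_BLOCKS)]
        mt_crit = mt[mt["block"].isin(CRITICAL_BLOCKS)]

        def per_subject(frame, measure, cond=None):
            sub = frame if cond is None else frame[frame["congruency"] == cond]
            if measure == "accuracy":
                return sub.groupby("subject")["correct"].mean()
            return sub.groupby("subject")["rt_ms"].median()

        rows = []
        for label, measure, cond in (
            ("total_accuracy", "accuracy", None),
            ("accuracy_congruent", "accuracy", "congruent"),
            ("accuracy_incongruent", "accuracy", "incongruent"),
            ("total_rt_ms", "rt", None),
            ("rt_congruent_ms", "rt", "congruent"),
            ("rt_incongruent_ms", "rt", "incongruent"),
        ):
            a = per_subject(kb_crit, measure, cond)
            b = per_subject(mt_crit, measure, cond)
            both = pd.concat([a.rename("rt_task"), b.rename("mt_task")], axis=1).dropna()
            try:
                w, r, p = mstats.paired_wilcoxon(
                    both["rt_task"].to_numpy(), both["mt_task"].to_numpy()
                )
            except ValueError:
                w, r, p = np.nan, np.nan, np.nan
            rows.append(
                dict(
                    measure=label,
                    rt_task_median=float(both["rt_task"].median()),
                    mt_task_median=float(both["mt_task"].median()),
                    W=w,
                    r=r,
                    p=p,
                    n=len(both),
                )
            )
        return pd.DataFrame(rows)


@dataclass
class RaceIATResults:
    """Fitted results of the joint race-IAT analysis."""

    model: RaceIAT
    d_scores: pd.DataFrame
    exclusions: ExclusionReport
    metrics: pd.DataFrame
    delta_md: pd.DataFrame
    delta_acc_max_time: pd.DataFrame
    interaction_md: dict
    interaction_acc_max_time: dict
    contrast_md: pd.DataFrame
    contrast_acc_max_time: pd.DataFrame
    dip: dict
    phase_table: pd.DataFrame
    early_phase_test: dict
    phase_comparison: pd.DataFrame
    associations: dict
    task_comparison: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.d_scores["subject"].nunique()

    @property
    def mean_d(self) -> float:
        return float(self.d_scores["d"].mean())

    def phase_index_means(self) -> pd.Series:
        return self.phase_table[["early_index_ms", "mid_index_ms", "late_index_ms"]].mean()

    def largest_phase(self) -> str:
        means = self.phase_index_means()
        return str(means.idxmax()).replace("_index_ms", "")

    def summary(self) -> str:
        """Human-readable report of the main quantities."""
        lines = []
        push = lines.append
        push("Race-IAT mouse-tracking analysis")
        push("=" * 64)
        push(f"Subjects: {self.n_subjects}   kept critical trials: {len(self.metrics)}")
        push("")
        push("Keyboard D score (improved algorithm, + = pro-White direction)")
        d = self.d_scores["d"]
        push(f"  mean D = {d.mean():.3f}   SEM = {d.sem():.3f}   n = {len(d)}")
        push("")
        push("Trial exclusions (critical blocks)")
        for row in self.exclusions.frame.itertuples(index=False):
            push(
                f"  {row.congruency:<12} {row.pct_excluded:5.1f}% excluded "
                f"({row.n_incorrect} incorrect, {row.n_rt_outlier} RT outliers, "
                f"{row.n_it_too_long} slow initiations of {row.n_total})"
            )
        push("")
        push("Congruency effects (incongruent - congruent, subject means)")
        push(f"  delta MD           = {self.delta_md['delta_md'].mean():+.4f}")
        push(
            "  delta Acc-Max-Time = "
            f"{self.delta_acc_max_time['delta_acc_max_time_ms'].mean():+.1f} ms"
        )
        imd = self.interaction_md
        push(
            f"  attribute-by-race contrast (MD): t({imd['df']}) = {imd['t']:.2f}, "
            f"p = {imd['p']:.2g}"
        )
        push("")
        push("Dip test on z-transformed MD (H0: unimodal)")
        for cond, res in self.dip.items():
            push(f"  {cond:<12} d = {res.d:.4f}   p = {res.p:.3f}   n = {res.n}")
        push("")
        push("Conflict phases (incongruent - congruent indices)")
        means = self.phase_index_means()
        push(
            f"  early = {means['early_index_ms']:+.1f} ms   "
            f"mid = {means['mid_index_ms']:+.1f} ms   "
            f"late = {means['late_index_ms']:+.1f} ms   (largest: {self.largest_phase()})"
        )
        et = self.early_phase_test
        push(f"  early-phase t({et['df']}) = {et['t']:.2f}, p = {et['p']:.2g}")
        for row in self.phase_comparison.itertuples(index=False):
            push(
                f"  {row.pair:<11} mean diff = {row.mean_diff_ms:+7.1f} ms   "
                f"p_holm = {row.p_holm:.3g}"
            )
        push("")
        push("Associations with the D score (OLS slope b)")
        for name, res in self.associations.items():
            push(
                f"  {name:<20} b = {res.slope:7.2f}   t({res.df}) = {res.t:5.2f}   "
                f"p = {res.p:.3g}"
            )
        push("")
        push("Keyboard vs mouse task (paired Wilcoxon)")
        for row in self.task_comparison.itertuples(index=False):
            push(
                f"  {row.measure:<22} RT-task {row.rt_task_median:8.3f}   "
                f"MT-task {row.mt_task_median:8.3f}   W = {row.W:.1f}   "
                f"r = {row.r:+.3f}   p = {row.p:.2g}"
            )
        return "\n".join(lines)

    # --- plotting -----------------------------------------------------------

    def plot_mean_trajectories(self, ax=None):
        """Average remapped trajectory per congruency condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        batch_keys = self.metrics[["subject", "block", "trial", "congruency"]]
        # recompute normalized paths of kept trials for display
        crit = [
            tr
            for tr in self.model.trajectories
            if tr.block in CRITICAL_BLOCKS
        ]
        batch = preprocess_batch(crit, self.model.design)
        merged = batch.keys.merge(
            batch_keys, on=["subject", "block", "trial"], how="left"
        )
        for cond, color in (("congruent", "tab:blue"), ("incongruent", "tab:red")):
            mask = (merged["congruency"] == cond).to_numpy()
            if mask.any():
                ax.plot(
                    batch.x[mask].mean(axis=0),
                    batch.y[mask].mean(axis=0),
                    color=color,
                    label=cond,
                )
        ax.plot([batch.x[0, 0]], [batch.y[0, 0]], "ko")
        ax.set_xlabel("x (normalized)")
        ax.set_ylabel("y (normalized)")
        ax.legend()
        return ax

    def plot_phase_indices(self, ax=None):
        """Mean +/- SEM of the three phase indices."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cols = ["early_index_ms", "mid_index_ms", "late_index_ms"]
        means = self.phase_table[cols].mean()
        sems = self.phase_table[cols].sem()
        ax.errorbar(["Early", "Mid", "Late"], means, yerr=sems, marker="o")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_ylabel("Congruency effect (ms)")
        return ax
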