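"""Improved-algorithm IAT D score from keyboard critical-block trials.

The variant fixed here: delete trials slower than 10,000 ms; flag (not
drop) respondents with more than 10% of remaining trials faster than
300 ms; replace each error trial's latency with its block's correct-trial
mean plus a 600 ms penalty; then score each block pair as the incongruent
minus congruent mean divided by the pooled SD of all the pair's adjusted
latencies, and average the two pair scores.  Pairs are (block 3, block 6)
and (block 4, block 7); positive D codes the pro-White direction
(incongruent slower).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CRITICAL_BLOCKS

SLOW_CUTOFF_MS = 10_000.0
FAST_CUTOFF_MS = 300.0
FAST_FLAG_PROPORTION = 0.10
ERROR_PENALTY_MS = 600.0

BLOCK_PAIRS = ((3, 6), (4, 7))


@dataclass(frozen=True)
class DScoreResult:
    subject_id: str
    d: float
    d_pair1: float
    d_pair2: float
    n_trials_used: int
    n_deleted_slow: int
    fast_fraction: float
    flagged_fast: bool


def prepare_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Slow-trial deletion and fast-responding diagnostics.

    ``trials`` holds one subject's critical-block rows with ``block``,
    ``rt_ms`` and ``correct``.  Trials with rt > 10,000 ms are deleted; the
    fraction of remaining trials with rt < 300 ms is reported and the
    subject flagged when it exceeds 10%.
    """
    crit = trials[trials["block"].isin(CRITICAL_BLOCKS)]
    if len(crit) == 0:
        raise ValueError("no critical-block trials")
    kept = crit[crit["rt_ms"] <= SLOW_CUTOFF_MS]
    n_deleted = len(crit) - len(kept)
    fast_fraction = float((kept["rt_ms"] < FAST_CUTOFF_MS).mean()) if len(kept) else 0.0
    diagnostics = dict(
        n_deleted_slow=int(n_deleted),
        fast_fraction=fast_fraction,
        flagged_fast=bool(fast_fraction > FAST_FLAG_PROPORTION),
    )
    return kept, diagnostics


def error_penalty_replace(trials: pd.DataFrame, penalty: float = ERROR_PENALTY_MS) -> pd.DataFrame:
    """Replace error-trial latencies by block correct mean + penalty."""
    out = trials.copy()
    for block, grp in out.groupby("block"):
        correct = grp[grp["correct"].astype(bool)]
        errors = grp[~grp["correct"].astype(bool)]
        if len(errors) == 0:
            continue
        if len(correct) == 0:
            raise ValueError(f"block {block} has no correct trials to compute the penalty mean")
        out.loc[errors.index, "rt_ms"] = correct["rt_ms"].mean() + penalty
    return out


def _pair_score(trials: pd.DataFrame, congruent_block: int, incongruent_block: int) -> float:
    cong = trials.loc[trials["block"] == congruent_block, "rt_ms"]
    incong = trials.loc[trials["block"] == incongruent_block, "rt_ms"]
    if len(cong) == 0 or len(incong) == 0:
        raise ValueError(
            f"missing trials in block pair ({congruent_block}, {incongruent_block})"
        )
    pooled = pd.concat([cong, incong]).std(ddof=1)
    if not np.isfinite(pooled) or pooled == 0:
        raise ValueError(
            f"zero pooled SD in block pair ({congruent_block}, {incongruent_block})"
        )
    return float((incong.mean() - cong.mean()) / pooled)


def compute_d(adjusted: pd.DataFrame, subject_id: str | None = None) -> DScoreResult:
    """D score from penalty-adjusted critical-block trials."""
    if subject_id is None:
        subject_id = str(adjusted["subject"].iloc[0]) if "subject" in adjusted else ""
    d1 = _pair_score(adjusted, *BLOCK_PAIRS[0])
    d2 = _pair_score(adjusted, *BLOCK_PAIRS[1])
    return DScoreResult(
        subject_id=subject_id,
        d=(d1 + d2) / 2.0,
        d_pair1=d1,
        d_pair2=d2,
        n_trials_used=len(adjusted),
        n_deleted_slow=0,
        fast_fraction=0.0,
        flagged_fast=False,
    )


def score_subject(trials: pd.DataFrame, subject_id: str | None = None) -> DScoreResult:
    """Full improved-algorithm chain for one subject."""
    kept, diag = prepare_trials(trials)
    adjusted = error_penalty_replace(kept)
    res = compute_d(adjusted, subject_id=subject_id)
    return DScoreResult(
        subject_id=res.subject_id,
        d=res.d,
        d_pair1=res.d_pair1,
        d_pair2=res.d_pair2,
        n_trials_used=res.n_trials_used,
        n_deleted_slow=diag["n_deleted_slow"],
        fast_fraction=diag["fast_fraction"],
        flagged_fast=diag["flagged_fast"],
    )


def score_subjects(keyboard_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject D scores for a cohort's keyboard trial table."""
    rows = []
    for subject, grp in keyboard_trials.groupby("subject", sort=True):
        res = score_subject(grp, subject_id=str(subject))
        rows.append(
            dict(
                subject=subject,
                d=res.d,
                d_pair1=res.d_pair1,
                d_pair2=res.d_pair2,
                n_trials_used=res.n_trials_used,
                n_deleted_slow=res.n_deleted_slow,
                fast_fraction=res.fast_fraction,
                flagged_fast=res.flagged_fast,
            )
        )
    return pd.DataFrame(rows)
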