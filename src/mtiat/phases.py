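"""Early/Mid/Late decomposition of the congruency effect.

From each subject's per-condition means of initiation time (IT),
maximum-deviation time (MD-Time) and reaction time (RT), the trial
timeline splits into three intervals:

* Early = IT (stimulus onset to movement onset),
* Mid   = MD-Time - IT (movement onset to the point of highest attraction
  toward the incorrect response),
* Late  = RT - MD-Time (highest-attraction point to the response click).

The phase *indices* are the incongruent-minus-congruent differences of
those intervals; by construction their sum equals the RT congruency effect
exactly.
"""

from __future__ import annotations

import pandas as pd

PHASES = ("early", "mid", "late")


def condition_means(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-congruency means of IT, MD-Time and RT.

    ``metrics`` is the per-trial table of kept critical trials (columns
    ``subject, congruency, it_ms, md_time_ms, rt_ms``).
    """
    crit = metrics[metrics["congruency"].isin(["congruent", "incongruent"])]
    out = (
        crit.groupby(["subject", "congruency"])[["it_ms", "md_time_ms", "rt_ms"]]
        .mean()
        .reset_index()
    )
    return out


def phase_durations(cond_means: pd.DataFrame) -> pd.DataFrame:
    """Early/Mid/Late durations per subject and congruency condition.

    Requires both conditions for every subject; the additive identity
    ``early + mid + late = mean RT`` holds to machine precision.
    """
    counts = cond_means.groupby("subject")["congruency"].nunique()
    missing = counts[counts < 2]
    if len(missing) > 0:
        raise ValueError(
            f"subjects missing a congruency condition: {list(missing.index)}"
        )
    out = cond_means.copy()
    out["early_ms"] = out["it_ms"]
    out["mid_ms"] = out["md_time_ms"] - out["it_ms"]
    out["late_ms"] = out["rt_ms"] - out["md_time_ms"]
    return out[["subject", "congruency", "early_ms", "mid_ms", "late_ms", "rt_ms"]]


def phase_indices(durations: pd.DataFrame) -> pd.DataFrame:
    """Incongruent-minus-congruent phase indices per subject.

    ``early_index + mid_index + late_index`` equals each subject's RT
    congruency effect (``delta_rt_ms``) exactly.
    """
    wide = durations.pivot(index="subject", columns="congruency")
    out = pd.DataFrame(index=wide.index)
    for phase in PHASES:
        col = f"{phase}_ms"
        out[f"{phase}_index_ms"] = wide[(col, "incongruent")] - wide[(col, "congruent")]
    out["delta_rt_ms"] = wide[("rt_ms", "incongruent")] - wide[("rt_ms", "congruent")]
    return out.reset_index()


def phase_table(metrics: pd.DataFrame, on_missing: str = "error") -> pd.DataFrame:
    """Full chain: per-trial metrics -> per-subject phase indices.

    ``on_missing='drop'`` silently removes subjects lacking a condition
    (e.g. after exclusions) instead of raising.
    """
    means = condition_means(metrics)
    if on_missing == "drop":
        counts = means.groupby("subject")["congruency"].nunique()
        means = means[means["subject"].isin(counts[counts == 2].index)]
        if len(means) == 0:
            raise ValueError("no subject has both congruency conditions")
    return phase_indices(phase_durations(means))
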