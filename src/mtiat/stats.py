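"""Group-level inference: congruency contrasts, D-score associations,
factor congruence and task comparisons.

Mixed-model fits reported for designs like this one are replaced here by
within-subject cell-mean contrasts followed by one-sample tests, which for
balanced within-subject designs test the same directional hypotheses; the
three pairwise phase comparisons use Holm's correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .design import WHITE_POSITIVE, WHITE_NEGATIVE, BLACK_POSITIVE, BLACK_NEGATIVE


@dataclass(frozen=True)
class AssociationResult:
    """Simple linear regression of a per-subject response on the D score."""

    slope: float
    intercept: float
    t: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class CongruenceResult:
    """Tucker's congruence coefficients for matched factor pairs."""

    phi: np.ndarray  # per factor pair


# ---------------------------------------------------------------------------
# per-subject condition differences


def delta_scores(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-subject incongruent-minus-congruent mean of ``metric``.

    Subjects missing either condition are excluded (with a warning via the
    returned frame simply omitting them).
    """
    crit = metrics[metrics["congruency"].isin(["congruent", "incongruent"])]
    means = crit.groupby(["subject", "congruency"])[metric].mean().unstack()
    ok = means.dropna(subset=["congruent", "incongruent"])
    out = pd.DataFrame(
        {
            "subject": ok.index,
            f"delta_{metric}": (ok["incongruent"] - ok["congruent"]).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def cell_means(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-subject means of ``metric`` in the four attribute-by-race cells."""
    cells = [WHITE_POSITIVE, WHITE_NEGATIVE, BLACK_POSITIVE, BLACK_NEGATIVE]
    crit = metrics[metrics["condition"].isin(cells)]
    wide = crit.groupby(["subject", "condition"])[metric].mean().unstack()
    return wide.reindex(columns=cells)


def interaction_contrast(cells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Attribute-by-race interaction as a within-subject contrast.

    ``contrast = (WhiteNeg - WhitePos) - (BlackNeg - BlackPos)`` per
    subject; positive values mean more conflict when pairing White with
    negative than Black with negative -- the congruency pattern.  The group
    test is a one-sample t against zero.
    """
    ok = cells.dropna()
    contrast = (ok[WHITE_NEGATIVE] - ok[WHITE_POSITIVE]) - (
        ok[BLACK_NEGATIVE] - ok[BLACK_POSITIVE]
    )
    vals = contrast.to_numpy()
    if len(vals) >= 2 and vals.std(ddof=1) > 0:
        t, df, p = one_sample_t(vals)
    else:  # degenerate (constant contrast): no group test possible
        t, df, p = np.nan, len(vals) - 1, np.nan
    frame = pd.DataFrame({"subject": ok.index, "contrast": vals})
    return frame.reset_index(drop=True), dict(t=t, df=df, p=p, n=len(ok))


# ---------------------------------------------------------------------------
# elementary tests


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> tuple[float, int, float]:
    """Student's one-sample t-test; returns ``(t, df, two-sided p)``."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(x, mu0)
    return float(res.statistic), int(n - 1), float(res.pvalue)


def paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; requires n >= 5 afterwards.  The p-value
    uses the normal approximation with continuity and tie corrections; the
    effect size is ``r = Z / sqrt(n)`` with the sign of the (x - y) shift
    retained.  Returns ``(W, r, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    nz = diff[diff != 0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero")
    if len(nz) < 5:
        raise ValueError("fewer than 5 nonzero differences")
    res = sps.wilcoxon(nz, correction=True, method="approx")
    # the two-sided statistic is min(T+, T-), so its z never carries the
    # direction; re-attach the sign of the rank-sum shift
    ranks = sps.rankdata(np.abs(nz))
    t_plus = ranks[nz > 0].sum()
    mu = len(nz) * (len(nz) + 1) / 4
    sign = 1.0 if t_plus > mu else (-1.0 if t_plus < mu else 0.0)
    r = sign * abs(float(res.zstatistic)) / np.sqrt(len(nz))
    return float(res.statistic), float(r), float(res.pvalue)


def ols_association(d_scores: np.ndarray, response: np.ndarray) -> AssociationResult:
    """Least-squares regression of a per-subject response on the D score."""
    d = np.asarray(d_scores, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(d) != len(y):
        raise ValueError("d_scores and response must have equal length")
    if len(d) < 3:
        raise ValueError("need at least 3 subjects")
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance in D scores")
    model = sm.OLS(y, sm.add_constant(d)).fit()
    return AssociationResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        t=float(model.tvalues[1]),
        df=int(model.df_resid),
        p=float(model.pvalues[1]),
        n=len(d),
    )


def tucker_phi(loadings_a: np.ndarray, loadings_b: np.ndarray) -> CongruenceResult:
    """Tucker's congruence coefficient for matched factor columns.

    ``phi_k = sum_i a_ik b_ik / sqrt(sum_i a_ik^2 * sum_i b_ik^2)``;
    invariant to positive rescaling of either loading vector.
    """
    a = np.atleast_2d(np.asarray(loadings_a, dtype=float))
    b = np.atleast_2d(np.asarray(loadings_b, dtype=float))
    if a.shape[0] == 1:
        a, b = a.T, b.T
    if a.shape != b.shape:
        raise ValueError("loading matrices must have equal shape")
    na = np.sqrt((a**2).sum(axis=0))
    nb = np.sqrt((b**2).sum(axis=0))
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm loading vector")
    phi = (a * b).sum(axis=0) / (na * nb)
    return CongruenceResult(phi=phi)


# ---------------------------------------------------------------------------
# phase comparisons


def phase_contrasts(phase_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired t-tests between the three phase indices.

    Early-Mid, Early-Late and Mid-Late comparisons with Holm-corrected
    p-values; the largest-mean phase is reported by the caller from the
    table itself.
    """
    cols = {p: f"{p}_index_ms" for p in ("early", "mid", "late")}
    for c in cols.values():
        if c not in phase_table.columns:
            raise ValueError(f"phase table missing column {c}")
    pairs = [("early", "mid"), ("early", "late"), ("mid", "late")]
    rows = []
    for a, b in pairs:
        da = phase_table[cols[a]].to_numpy()
        db = phase_table[cols[b]].to_numpy()
        diff = da - db
        if diff.std(ddof=1) == 0:
            if diff.mean() != 0:
                raise ValueError(f"degenerate constant nonzero difference for {a}-{b}")
            t, df, p = 0.0, len(diff) - 1, 1.0
        else:
            t, df, p = one_sample_t(diff)
        rows.append(dict(pair=f"{a}-{b}", mean_diff_ms=float(diff.mean()), t=t, df=df, p=p))
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


def fdr_correct(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
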