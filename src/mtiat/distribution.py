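"""Unimodality testing: z-transform and Hartigan & Hartigan's dip statistic.

The dip of a sample is the maximum over the sorted points of the minimal
sup-norm distance between the empirical cdf and the class of unimodal
cdfs.  It is computed by the classic iterative construction: within a
shrinking candidate modal interval, fit the greatest convex minorant (GCM)
and least concave majorant (LCM) of the empirical cdf, measure their
largest separation, and accumulate the one-sided distances of the cdf from
the fits outside the modal interval until the separation no longer exceeds
the accumulated dip.  The statistic is affine-invariant and bounded by
[1/(2n), 1/4].

p-values are Monte-Carlo, simulated under the uniform null -- the
least-favourable unimodal distribution for the dip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to z-transform")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigan & Hartigan's dip of a univariate sample.

    Requires at least 4 finite values.  Distances are accumulated in
    "count" units internally and divided by 2n at the end, so a perfectly
    uniform lattice attains the lower bound 1/(2n).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("dip requires at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # 1-based arrays to keep the index arithmetic transparent
    xs = np.empty(n + 1)
    xs[1:] = x
    low, high = 1, n
    dip = 1.0  # count units; lower bound after the final /(2n)

    mn = np.zeros(n + 1, dtype=int)
    mj = np.zeros(n + 1, dtype=int)

    for _ in range(2 * n + 10):  # the modal interval strictly shrinks
        # greatest convex minorant touch indices on [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if (xs[j] - xs[mnj]) * (mnj - mnmnj) < (xs[mnj] - xs[mnmnj]) * (j - mnj):
                    break
                mn[j] = mnmnj
        # least concave majorant touch indices on [low, high]
        mj[high] = high
        for j in range(high - 1, low - 1, -1):
            mj[j] = j + 1
            while True:
                mjk = mj[j]
                if mjk == high:
                    break
                mjmjk = mj[mjk]
                if (xs[j] - xs[mjk]) * (mjk - mjmjk) < (xs[mjk] - xs[mjmjk]) * (j - mjk):
                    break
                mj[j] = mjmjk

        # collect touch points: gcm from high down to low, lcm low up to high
        gcm = [0, high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm) - 1
        lcm = [0, low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm) - 1

        ig, ih = l_gcm, l_lcm
        ix, iv = l_gcm - 1, 2
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # LCM touch point against the GCM chord through it
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # GCM touch point against the LCM chord through it
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # one-sided dips of the cdf from the fits outside the new interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t
        dip = max(dip, dip_l, dip_u)

        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high
    return dip / (2.0 * n)


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its Monte-Carlo p-value."""

    d: float
    p: float
    n: int
    n_boot: int
    seed: int | None


def uniform_null_dips(n: int, n_boot: int = 2000, seed: int | None = None) -> np.ndarray:
    """Monte-Carlo null distribution of the dip at sample size ``n``."""
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(
    sample: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    null_dips: np.ndarray | None = None,
) -> DipResult:
    """Dip test of unimodality with a uniform-null Monte-Carlo p-value.

    ``p`` is the proportion of ``n_boot`` uniform samples of the same size
    whose dip is at least the observed one.  A precomputed ``null_dips``
    array (from :func:`uniform_null_dips` at the same n) can be supplied to
    amortise the simulation across repeated tests.
    """
    d = dip_statistic(sample)
    if null_dips is None:
        null_dips = uniform_null_dips(len(sample), n_boot=n_boot, seed=seed)
    p = float(np.mean(null_dips >= d))
    return DipResult(d=d, p=p, n=len(np.asarray(sample)), n_boot=len(null_dips), seed=seed)
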