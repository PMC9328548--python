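"""Independent linear-programming oracle for the dip statistic.

The dip of an empirical cdf F_n is min_G sup_x |F_n(x) - G(x)| over
unimodal cdfs G.  For small n this is solvable exactly: the optimal G can
be taken piecewise linear with knots at the data points, continuous except
for a possible atom at the mode.  For every candidate mode placement we
minimise t subject to linear band, monotonicity and convex/concave shape
constraints, and take the minimum over placements:

* mode at data point x_k with a possible atom: split G(x_k) into a left
  limit and a value, convexity ending at the left limit, concavity
  starting at the value.

Modes interior to a gap between data points are dominated by the two
flanking mode-at-knot placements (the growth requirement over the gap is
linear in the mode location, so its minimum sits at an endpoint), so
scanning the data points is exhaustive.

Band constraints encode the sup over all real x: at each knot the cdf's
upper and lower step levels must both be within t of G, plus the tail
conditions G(x_1^-) <= t and 1 - G(x_n) <= t.

Exact but O(n) LPs of O(n) variables -- a few seconds for n <= 30.  Used
only as a test oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(c, A_ub, b_ub):
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=[(None, None)] * len(c))
    if not res.success:
        return np.inf
    return res.fun


def _point_mode_lp(x: np.ndarray, k: int) -> float:
    """Mode at data point x_k with a possible atom (0-based k)."""
    n = len(x)
    # variables g_0..g_{n-1} (cdf values; at k this is the value after the
    # jump), plus l = left limit at x_k, plus t
    l_ix, t_ix = n, n + 1
    c = np.zeros(n + 2)
    c[t_ix] = 1.0
    A, b = [], []

    def row():
        return np.zeros(n + 2)

    for i in range(n):
        up = (i + 1) / n
        lo = i / n
        # value at knot within t of the upper level (F right-continuous)
        r = row(); r[i] = 1.0; r[t_ix] = -1.0; A.append(r); b.append(up)
        r = row(); r[i] = -1.0; r[t_ix] = -1.0; A.append(r); b.append(-up)
        # left limit within t of lower level
        j = l_ix if i == k else i
        r = row(); r[j] = 1.0; r[t_ix] = -1.0; A.append(r); b.append(lo)
        r = row(); r[j] = -1.0; r[t_ix] = -1.0; A.append(r); b.append(-lo)
    # tails and monotonicity
    r = row(); r[0 if k != 0 else l_ix] = 1.0; r[t_ix] = -1.0; A.append(r); b.append(0.0)
    r = row(); r[n - 1] = -1.0; r[t_ix] = -1.0; A.append(r); b.append(-1.0)
    for i in range(n - 1):
        hi = l_ix if i + 1 == k else i + 1
        r = row(); r[i] = 1.0; r[hi] = -1.0; A.append(r); b.append(0.0)
    r = row(); r[l_ix] = 1.0; r[k] = -1.0; A.append(r); b.append(0.0)  # jump >= 0
    r = row(); r[0 if k != 0 else l_ix] = -1.0; A.append(r); b.append(0.0)
    r = row(); r[n - 1] = 1.0; A.append(r); b.append(1.0)

    dx = np.diff(x)

    def seg_vars(i):
        # endpoint variable indices of segment i under the split at k
        a = i
        bb = i + 1
        if i + 1 == k:
            bb = l_ix  # segment ending at the mode uses the left limit
        if i == k:
            a = k  # segment starting at the mode uses the (post-jump) value
        return a, bb

    def slope_pair(i, j, sign):
        ai, bi = seg_vars(i)
        aj, bj = seg_vars(j)
        r = row()
        r[ai] -= sign / dx[i]
        r[bi] += sign / dx[i]
        r[aj] += sign / dx[j]
        r[bj] -= sign / dx[j]
        A.append(r)
        b.append(0.0)

    for i in range(0, k - 1):
        if i + 1 <= k - 1:
            slope_pair(i, i + 1, +1.0)
    for i in range(k, n - 2):
        slope_pair(i, i + 1, -1.0)
    return _solve(c, A, b)


def dip_lp(sample: np.ndarray) -> float:
    """Exact dip by exhaustive LP over mode placements."""
    x = np.sort(np.asarray(sample, dtype=float))
    if len(np.unique(x)) != len(x):
        raise ValueError("LP oracle requires tie-free samples")
    best = np.inf
    for k in range(len(x)):
        best = min(best, _point_mode_lp(x, k))
    return float(best)
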