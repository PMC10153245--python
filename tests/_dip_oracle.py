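"""Independent brute-force oracle for the dip statistic.

The dip of an empirical CDF F_n is min over unimodal CDFs G of sup|F_n - G|.
This oracle solves that minimisation directly as a family of linear programs,
one per candidate modal position, over the values of G at the sample points:

* a unimodal CDF is convex up to its mode and concave after it, continuous
  everywhere except possibly a jump at the mode;
* for distinct sorted data the sup distance constraint ``sup|F_n - G| <= t``
  reduces to box constraints at the sample points: away from the mode,
  ``i/n - t <= G(x_i) <= (i-1)/n + t`` (the upper bound from the left limit
  of F_n); at a modal sample point the jump splits the two constraints
  between the left limit and the value of G;
* convexity/concavity become ordered chord-slope constraints, and G must be
  nondecreasing in [0, 1].

Minimising t for every modal placement (each inter-point interval and each
sample point with a jump) and taking the smallest optimum gives the exact
dip up to LP solver accuracy.  This is deliberately algorithmically
unrelated to the iterative greatest-convex-minorant implementation in
``lysoscape.dip`` and is practical only for small n.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve_mode_lp(x, n, j_mode, point_mode, link=None):
    """Min sup-distance for one modal placement.

    Variables: t, g_1..g_n, and (for a point mode) h = left limit of G at the
    modal sample point.  ``j_mode`` is the 0-based index of the last convex
    point; for an interval mode the convex side is 0..j_mode and the concave
    side j_mode+1..n-1 (j_mode = -1: all concave; j_mode = n-1: all convex).
    """
    nv = 1 + n + (1 if point_mode else 0)
    c = np.zeros(nv)
    c[0] = 1.0  # minimise t
    A_ub, b_ub = [], []

    def g(i):  # column index of g_i
        return 1 + i

    h_col = 1 + n if point_mode else None

    def add(coefs, rhs):
        row = np.zeros(nv)
        for col, v in coefs:
            row[col] += v
        A_ub.append(row)
        b_ub.append(rhs)

    # Deviation boxes. F(x_i) = (i+1)/n, F(x_i^-) = i/n  (0-based i).
    for i in range(n):
        fi = (i + 1) / n
        fim = i / n
        if point_mode and i == j_mode:
            # value constrained against F(x_i); left limit h against F(x_i^-)
            add([(g(i), -1.0), (0, -1.0)], -fi)   # g_i >= fi - t
            add([(g(i), 1.0), (0, -1.0)], fi)     # g_i <= fi + t
            add([(h_col, -1.0), (0, -1.0)], -fim)
            add([(h_col, 1.0), (0, -1.0)], fim)
        else:
            add([(g(i), -1.0), (0, -1.0)], -fi)   # g_i >= fi - t
            add([(g(i), 1.0), (0, -1.0)], fim)    # g_i <= fim + t

    # Monotone nondecreasing, with h between g_{j-1} and g_j at a point mode.
    for i in range(n - 1):
        if point_mode and i + 1 == j_mode:
            add([(g(i), 1.0), (h_col, -1.0)], 0.0)
            add([(h_col, 1.0), (g(i + 1), -1.0)], 0.0)
        else:
            add([(g(i), 1.0), (g(i + 1), -1.0)], 0.0)

    def chord_le(ia, ca, ib, cb, ic, cc):
        # slope(a->b) <= slope(b->c) for columns ca, cb, cc at x positions ia, ib, ic
        dab = x[ib] - x[ia]
        dbc = x[ic] - x[ib]
        # (gb - ga)/dab <= (gc - gb)/dbc  ->  (gb-ga)*dbc - (gc-gb)*dab <= 0
        add([(cb, dbc + dab), (ca, -dbc), (cc, -dab)], 0.0)

    if point_mode:
        conv = list(range(0, j_mode)) + [("h", j_mode)]
        conc = list(range(j_mode, n))
    else:
        conv = list(range(0, j_mode + 1))
        conc = list(range(j_mode + 1, n))

    def col_of(item):
        if isinstance(item, tuple):
            return h_col
        return g(item)

    def idx_of(item):
        if isinstance(item, tuple):
            return item[1]
        return item

    for a, b, cpt in zip(conv, conv[1:], conv[2:]):
        chord_le(idx_of(a), col_of(a), idx_of(b), col_of(b), idx_of(cpt), col_of(cpt))
    for a, b, cpt in zip(conc, conc[1:], conc[2:]):
        # concave: slope(a->b) >= slope(b->c)
        ia, ib, ic = idx_of(a), idx_of(b), idx_of(cpt)
        ca, cb, cc = col_of(a), col_of(b), col_of(cpt)
        dab = x[ib] - x[ia]
        dbc = x[ic] - x[ib]
        add([(cb, -(dbc + dab)), (ca, dbc), (cc, dab)], 0.0)

    # For an interval mode in (x_j, x_{j+1}) with a jump at the mode, the
    # chord between g_j and g_{j+1} must continue either the convex chain
    # (mode close to x_j) or the concave chain (mode close to x_{j+1});
    # the caller enumerates both variants.
    if not point_mode and link == "conv" and j_mode >= 1:
        chord_le(j_mode - 1, g(j_mode - 1), j_mode, g(j_mode), j_mode + 1, g(j_mode + 1))
    if not point_mode and link == "conc" and j_mode + 2 <= n - 1:
        ia, ib, ic = j_mode, j_mode + 1, j_mode + 2
        dab = x[ib] - x[ia]
        dbc = x[ic] - x[ib]
        add([(g(ib), -(dbc + dab)), (g(ia), dbc), (g(ic), dab)], 0.0)

    bounds = [(0, None)] + [(0.0, 1.0)] * (nv - 1)
    res = linprog(
        c,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-10, "dual_feasibility_tolerance": 1e-10},
    )
    if not res.success:
        return np.inf
    return res.fun


def dip_bruteforce(sample) -> float:
    """Exact dip of a sample with distinct values, by exhaustive LP."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.unique(x).size != n:
        raise ValueError("oracle requires distinct values")
    best = np.inf
    for j in range(-1, n):  # interval modes (j = last convex point)
        if -1 < j < n - 1:
            best = min(best, _solve_mode_lp(x, n, j, point_mode=False, link="conv"))
            best = min(best, _solve_mode_lp(x, n, j, point_mode=False, link="conc"))
        else:
            best = min(best, _solve_mode_lp(x, n, j, point_mode=False))
    for j in range(n):  # point modes with a jump at x_j
        best = min(best, _solve_mode_lp(x, n, j, point_mode=True))
    return float(best)
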