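"""Hartigan & Hartigan's dip statistic and a Monte-Carlo dip test.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function.  It is computed
exactly by the iterative modal-interval algorithm: alternately fit the
greatest convex minorant (GCM) below the modal interval and the least concave
majorant (LCM) above it, measure the largest discrepancy between the two
fits, and shrink the candidate modal interval until the discrepancy no longer
exceeds the dip accumulated so far.

The p-value is estimated by Monte-Carlo sampling of the dip under a
uniform(0, 1) null of the same sample size, which is the asymptotically
least-favourable unimodal null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_test"]

#: Largest sample the Monte-Carlo test will consume before subsampling.
MAX_DIP_SAMPLE = 80_000


@dataclass(frozen=True)
class DipResult:
    """Outcome of a Monte-Carlo dip test."""

    dip: float
    p_value: float
    n: int
    n_boot: int
    seed: int | None


def dip_statistic(sample) -> float:
    """Exact dip statistic of a one-dimensional sample.

    Parameters
    ----------
    sample:
        At least four finite real values (any order, ties allowed).

    Returns
    -------
    float
        The dip, in [1/(2n), 0.25].  A perfectly unimodal empirical
        distribution attains the lower bound 1/(2n).
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 4:
        raise ValueError(f"dip statistic requires n >= 4 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    x = np.sort(x)
    return _dip_sorted(x)


def _dip_sorted(xs: np.ndarray) -> float:
    """Dip of an already-sorted sample (the modal-interval algorithm).

    Indices are kept 1-based internally (x[1..n]) to mirror the classical
    formulation of the algorithm.
    """
    n = xs.size
    if xs[0] == xs[n - 1]:
        return 1.0 / (2.0 * n)
    x = np.empty(n + 1)
    x[1:] = xs

    # Pooled-slope predecessor indices for the GCM over the full sample:
    # mn[j] is the previous touch point of the greatest convex minorant.
    mn = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # Successor indices for the LCM, symmetric construction from the top.
    mj = np.empty(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in units of counts; >= 1 enforces the 1/(2n) floor
    gcm = np.empty(n + 2, dtype=np.int64)  # 1-based change-point arrays
    lcm = np.empty(n + 2, dtype=np.int64)

    while True:
        # Change points of the GCM from high down to low, LCM from low up.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i

        if l_gcm == 2 and l_lcm == 2:
            d = 1.0
        else:
            # Largest vertical gap between the GCM and LCM curves, in counts.
            d = 0.0
            ix = ig - 1
            iv = 2
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # the next change point is from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # the next change point is from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
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

        if d < dip:
            break

        # Maximum deviation of F from the GCM fit below the modal interval...
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb = gcm[j + 1]
            je = gcm[j]
            temp = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jr in range(jb, je + 1):
                    t = (jr - jb + 1) - (x[jr] - x[jb]) * c
                    if temp < t:
                        temp = t
            if dip_l < temp:
                dip_l = temp

        # ... and of F from the LCM fit above it.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb = lcm[j]
            je = lcm[j + 1]
            temp = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jr in range(jb, je + 1):
                    t = (x[jr] - x[jb]) * c - (jr - jb - 1)
                    if temp < t:
                        temp = t
            if dip_u < temp:
                dip_u = temp

        dip = max(dip, dip_l, dip_u)
        low_old, high_old = low, high
        low = int(gcm[ig])
        high = int(lcm[ih])
        if low == low_old and high == high_old:
            break

    return dip / (2.0 * n)


def dip_test(
    sample,
    n_boot: int = 2000,
    seed: int | None = None,
    null_dips: np.ndarray | None = None,
) -> DipResult:
    """Monte-Carlo dip test for unimodality.

    The p-value is the proportion of ``n_boot`` dip statistics from
    uniform(0, 1) samples of the same size that exceed the observed dip.
    Samples larger than 80,000 values are randomly subsampled to that size
    before testing.

    Parameters
    ----------
    null_dips:
        Optional precomputed table of null dip statistics for this sample
        size; when given, ``n_boot`` is ignored and no simulation is run.
        Useful when testing many samples of a common size.
    """
    x = np.asarray(sample, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    if x.size > MAX_DIP_SAMPLE:
        x = rng.choice(x, size=MAX_DIP_SAMPLE, replace=False)
    n = int(x.size)
    observed = dip_statistic(x)
    if null_dips is None:
        null_dips = simulate_null_dips(n, n_boot, rng)
    else:
        null_dips = np.asarray(null_dips, dtype=float)
    p = float(np.mean(null_dips > observed))
    return DipResult(dip=observed, p_value=p, n=n, n_boot=int(null_dips.size), seed=seed)


def simulate_null_dips(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform(0,1) samples of size ``n``."""
    out = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        u = np.sort(rng.random(n))
        out[b] = _dip_sorted(u)
    return out
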