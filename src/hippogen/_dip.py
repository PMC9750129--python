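"""Hartigan's dip statistic for unimodality.

The dip of an empirical distribution is the smallest sup-norm distance
between its CDF and the closest unimodal CDF, times one; large dips
indicate multimodality.  This is a direct port of the classical DIPTST
algorithm (Hartigan & Hartigan 1985), which alternates greatest-convex-
minorant / least-concave-majorant fits over a shrinking modal interval.

``dip_pvalue`` calibrates the statistic by Monte Carlo against the uniform
null, the least-favourable unimodal distribution.
"""

from __future__ import annotations

import numpy as np


def dip_statistic(samples) -> float:
    """Hartigan's dip of a 1-D sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n <= 3 or x[0] == x[-1]:
        return _small_dip(n)

    low, high = 0, n - 1
    dip = 1.0 / n  # lower bound attained by point masses

    # mn[j]: start index of the GCM segment ending at j (computed once, on
    # the full sample; segments restricted to [low, high] remain valid).
    mn = np.zeros(n, dtype=np.int64)
    mj = np.zeros(n, dtype=np.int64)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    while True:
        # GCM change points from high down to low; LCM from low up to high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)

        ix = l_gcm - 2
        iv = 1
        ig = l_gcm - 1
        ih = l_lcm - 1
        d = 0.0
        if not (l_gcm == 2 and l_lcm == 2):
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) / n - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        n * (x[gcmix] - x[gcmi1])
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        n * (x[lcmiv] - x[lcmiv1])
                    ) - (gcmix - lcmiv1 - 1) / n
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        if d < dip:
            break

        # dip within the convex minorant section
        dl = 0.0
        for j in range(ig, l_gcm - 1):
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (n * (x[je] - x[jb]))
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) / n - (x[jj] - x[jb]) * C
                    if t > dl:
                        dl = t
        # dip within the concave majorant section
        du = 0.0
        for j in range(ih, l_lcm - 1):
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (n * (x[je] - x[jb]))
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1) / n
                    if t > du:
                        du = t
        dipnew = max(dl, du)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return 0.5 * dip


def _small_dip(n: int) -> float:
    # dip of any sample of size <= 3 (or all-equal sample)
    return 0.5 / n if n >= 2 else 0.0


def dip_pvalue(samples, rng, n_boot: int = 1000) -> tuple[float, float]:
    """Dip statistic and Monte Carlo p-value under the uniform null.

    Returns (dip, p).  ``rng`` is a numpy Generator or seed.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(samples, dtype=float)
    n = len(x)
    stat = dip_statistic(x)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = dip_statistic(rng.random(n))
    p = float((1 + (boots >= stat).sum()) / (n_boot + 1))
    return stat, p
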