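"""Hartigan & Hartigan dip statistic for unimodality.

The dip of a sample is the maximum difference between its empirical CDF and
the closest unimodal CDF, the classic sup-norm test statistic for
multimodality.  ``dip_statistic`` is an O(n) greatest-convex-minorant /
least-concave-majorant alternation over the sorted sample (the standard
published algorithm); ``exact_dip`` in :mod:`felicore._dip_oracle` solves
the same minimization as a linear program and is used as a slow
cross-check.

The statistic is a rank statistic: it depends only on the order pattern of
the values, is invariant under strictly increasing transforms, and is
bounded below by 1/(2n), attained by perfectly unimodal configurations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(values) -> float:
    """Dip statistic of a sample (n >= 4 required).

    Works in "count" units internally (empirical CDF scaled by n) and
    divides by 2n at the end, so the minimum attainable value is 1/(2n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if x[0] == x[-1]:
        return 0.0

    low, high = 0, n - 1
    dip = 1.0  # count units; final statistic = dip / (2n)
    mn = np.empty(n, dtype=np.int64)
    mj = np.empty(n, dtype=np.int64)
    gcm = np.empty(n + 1, dtype=np.int64)
    lcm = np.empty(n + 1, dtype=np.int64)

    while True:
        # greatest convex minorant over [low, high]: mn[j] = predecessor of j
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                    break
                mn[j] = mnmnj
        # least concave majorant over [low, high]: mj[k] = successor of k
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                if mjk == high:
                    break
                mjmjk = mj[mjk]
                if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                    break
                mj[k] = mjmjk

        # change points of the GCM from high down to low, and LCM from low up
        gcm[0] = high
        i = 0
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i  # gcm[l_gcm] == low
        ix = ig - 1

        lcm[0] = low
        i = 0
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i  # lcm[l_lcm] == high
        iv = 1

        # largest vertical distance between the two fitted curves
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # dip within the convex-minorant side, outside the new modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # dip within the concave-majorant side
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_u if dip_u > dip_l else dip_l
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)
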