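"""Exact (slow) dip computation by linear programming.

The dip statistic is ``min over unimodal CDFs G of sup |F_n - G|``.  An
optimal G may be taken piecewise linear with knots at the distinct sample
values plus one knot at the mode, where the single jump is allowed.  For a
fixed mode abscissa the minimization is a linear program: the knot values
left of the mode form a nondecreasing convex chain, those right of it a
nondecreasing concave chain (both including the segments that connect to
the mode), with band constraints |F_n - G| <= d at every knot, and the
objective minimizes d.  The dip is the minimum over mode placements: the
mode at each distinct value (with the jump there), or strictly between two
values, where the abscissa is optimized numerically (coarse grid plus
golden-section refinement of the inner LP value).

This transcribes the definition directly and serves as the independent,
O(hundreds of LPs) oracle for the fast alternating-minorant implementation
in :mod:`felicore._dip`; it is far too slow for permutation testing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["exact_dip"]


def _solve(v: np.ndarray, c: np.ndarray, c_prev: np.ndarray, split: int,
           mode_x: float | None, mode_at_knot: bool) -> float:
    """Min sup-distance for one mode placement; returns inf if infeasible.

    ``split`` = index of the last knot served by the convex side.  With
    ``mode_at_knot`` the mode sits at knot ``split + 1`` (jump there, the
    convex side contributes only the left limit ``h``); otherwise the mode
    sits at ``mode_x`` strictly between knots split and split + 1, adding a
    pre-jump value ``h`` and post-jump value ``Z`` at that abscissa.
    """
    m = v.size
    left = list(range(split + 1))
    right = list(range(split + 1, m))

    # variable layout: [y_0..y_{m-1}, h, Z, d]
    nv = m + 3
    H, Zc, D = m, m + 1, m + 2
    A: list[np.ndarray] = []
    b: list[float] = []

    def le(coefs: dict[int, float], rhs: float) -> None:
        row = np.zeros(nv)
        for k, val in coefs.items():
            row[k] = val
        A.append(row)
        b.append(rhs)

    # band constraints at the data knots; with the jump at knot split+1 its
    # post-jump value is bounded by its own F value, not the left limit's
    for k in range(m):
        le({k: -1.0, D: -1.0}, -c[k])      # y_k >= c_k - d
        if not (mode_at_knot and k == split + 1):
            le({k: 1.0, D: -1.0}, c_prev[k])   # y_k <= c_{k-1} + d

    # geometry of the convex side: chain of (x, value) pairs
    if mode_at_knot:
        # h is the left limit at knot split+1; knot split+1 itself belongs
        # to the concave side with a relaxed upper band (value after jump)
        cx = [v[k] for k in left] + [v[split + 1]]
        cidx = left + [H]
        le({H: 1.0, D: -1.0}, c_prev[split + 1])   # h <= c_split + d
        # concave side's first knot: upper band uses its own F value
        k0 = split + 1
        le({k0: 1.0, D: -1.0}, c[k0])              # overrides via extra slack
        jump_from, jump_to = (left[-1] if left else None), k0
        rx = [v[k] for k in right]
        ridx = list(right)
    else:
        cx = [v[k] for k in left] + [mode_x]
        cidx = left + [H]
        le({H: 1.0, D: -1.0}, c[split])            # h <= c_split + d
        le({Zc: 1.0, D: -1.0}, c[split])           # Z <= c_split + d
        le({H: 1.0, Zc: -1.0}, 0.0)                # jump up: h <= Z
        jump_from, jump_to = None, None
        rx = [mode_x] + [v[k] for k in right]
        ridx = [Zc] + list(right)

    if not left:
        # no convex side: drop h from the chain
        cx, cidx = [], []

    # monotone + shape rows
    def chain(xs: list[float], idx: list[int], convex: bool) -> None:
        for a_i, b_i in zip(idx, idx[1:]):
            le({a_i: 1.0, b_i: -1.0}, 0.0)
        for (i0, i1, i2), (x0, x1, x2) in zip(
            zip(idx, idx[1:], idx[2:]), zip(xs, xs[1:], xs[2:])
        ):
            h1, h2 = x1 - x0, x2 - x1
            coefs = {i0: -h2, i1: h1 + h2, i2: -h1}
            if not convex:
                coefs = {k: -val for k, val in coefs.items()}
            le(coefs, 0.0)

    chain(cx, cidx, convex=True)
    chain(rx, ridx, convex=False)
    if mode_at_knot and jump_from is not None:
        le({jump_from: 1.0, H: -1.0}, 0.0)         # y_last <= h
    if mode_at_knot:
        le({H: 1.0, jump_to: -1.0}, 0.0)           # h <= z_{split+1}

    cost = np.zeros(nv)
    cost[D] = 1.0
    bounds = [(0.0, 1.0)] * (m + 2) + [(0.0, 1.0)]
    res = linprog(cost, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    return float(res.fun) if res.success else np.inf


def _plain_chain(v, c, c_prev, convex: bool) -> float:
    """Mode beyond the data: one all-convex or all-concave chain."""
    m = v.size
    nv = m + 1
    D = m
    A, b = [], []

    def le(coefs, rhs):
        row = np.zeros(nv)
        for k, val in coefs.items():
            row[k] = val
        A.append(row)
        b.append(rhs)

    for k in range(m):
        le({k: -1.0, D: -1.0}, -c[k])
        le({k: 1.0, D: -1.0}, c_prev[k])
    for a_i, b_i in zip(range(m), range(1, m)):
        le({a_i: 1.0, b_i: -1.0}, 0.0)
    for k in range(m - 2):
        h1, h2 = v[k + 1] - v[k], v[k + 2] - v[k + 1]
        coefs = {k: -h2, k + 1: h1 + h2, k + 2: -h1}
        if not convex:
            coefs = {kk: -val for kk, val in coefs.items()}
        le(coefs, 0.0)
    cost = np.zeros(nv)
    cost[D] = 1.0
    res = linprog(cost, A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(0.0, 1.0)] * nv, method="highs")
    return float(res.fun) if res.success else np.inf


def exact_dip(values, grid: int = 17, refine_iter: int = 60) -> float:
    """Dip of a sample by LP minimization over unimodal CDFs."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 4:
        raise ValueError("dip needs at least 4 observations")
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    c = np.cumsum(counts) / x.size
    c_prev = np.concatenate([[0.0], c[:-1]])

    best = min(_plain_chain(v, c, c_prev, convex=True),
               _plain_chain(v, c, c_prev, convex=False))

    # mode exactly at an interior-or-edge knot, jump allowed there
    for k in range(m):
        best = min(best, _solve(v, c, c_prev, split=k - 1, mode_x=None,
                                mode_at_knot=True))

    # mode strictly between consecutive knots: optimize the abscissa
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    for j in range(m - 1):
        lo, hi = v[j], v[j + 1]
        eps = 1e-9 * (hi - lo)
        ts = np.linspace(lo + eps, hi - eps, grid)
        vals = [_solve(v, c, c_prev, j, t, False) for t in ts]
        i = int(np.argmin(vals))
        a = ts[max(i - 1, 0)]
        b = ts[min(i + 1, grid - 1)]
        # golden-section refinement of the inner LP value
        c1 = b - gr * (b - a)
        c2 = a + gr * (b - a)
        f1 = _solve(v, c, c_prev, j, c1, False)
        f2 = _solve(v, c, c_prev, j, c2, False)
        for _ in range(refine_iter):
            if f1 <= f2:
                b, c2, f2 = c2, c1, f1
                c1 = b - gr * (b - a)
                f1 = _solve(v, c, c_prev, j, c1, False)
            else:
                a, c1, f1 = c1, c2, f2
                c2 = a + gr * (b - a)
                f2 = _solve(v, c, c_prev, j, c2, False)
            if b - a < 1e-12 * (hi - lo):
                break
        best = min(best, min(vals), f1, f2)
    return float(best)
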