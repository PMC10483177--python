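"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths they check: dense numpy linear
algebra instead of sparse solvers, explicit breakpoint summation instead of
the package's restriction/integration helpers.
"""

import numpy as np


def dense_als(y, lam, p, max_iter=20, tol=1e-6):
    """Asymmetric-least-squares baseline via dense penalized WLS.

    Same mathematical iteration as the package's sparse fit, solved with
    ``numpy.linalg.solve`` on explicit dense matrices.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i] = 1.0
        d2[i, i + 1] = -2.0
        d2[i, i + 2] = 1.0
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = None
    for _ in range(max_iter):
        z_new = np.linalg.solve(np.diag(w) + penalty, w * y)
        if z is not None:
            denom = np.linalg.norm(z)
            if np.linalg.norm(z_new - z) / (denom if denom > 0 else 1.0) < tol:
                return z_new
        z = z_new
        w = np.where(y > z, p, 1.0 - p)
    return z


def piecewise_linear_integral(x, y, lo, hi):
    """Exact integral over [lo, hi] of the piecewise-linear interpolant.

    Evaluates the interpolant on the union of a fine grid, the original
    breakpoints and the bounds, then sums trapezoids — exact because every
    kink is a grid node.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    inner = x[(x > lo) & (x < hi)]
    grid = np.unique(np.concatenate([np.linspace(lo, hi, 1001), inner]))
    vals = np.interp(grid, x, y)
    return float(np.sum((vals[1:] + vals[:-1]) / 2.0 * np.diff(grid)))


def intervals_tile(intervals, first_start, x_end, tol=1e-9):
    """Exhaustive interval-arithmetic check that intervals tile the span."""
    if not intervals:
        return first_start == x_end
    ivs = sorted(intervals, key=lambda iv: iv.start_ml)
    if abs(ivs[0].start_ml - first_start) > tol:
        return False
    if abs(ivs[-1].end_ml - x_end) > tol:
        return False
    for a, b in zip(ivs, ivs[1:]):
        if abs(a.end_ml - b.start_ml) > tol:  # gap or overlap
            return False
    for a in ivs:
        if a.start_ml >= a.end_ml:
            return False
    width = sum(iv.end_ml - iv.start_ml for iv in ivs)
    return abs(width - (x_end - first_start)) <= tol * max(1.0, abs(x_end))
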