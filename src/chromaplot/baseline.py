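"""Baseline estimation by asymmetric least squares (ALS).

The baseline of a chromatogram — buffer absorbance and detector drift — is
estimated with the Whittaker smoother under asymmetric weights
(Eilers-style ALS), the standard choice for chromatographic traces.  The
fit minimises

    sum_i w_i (y_i - z_i)^2  +  lambda * sum_i (Delta^2 z_i)^2

where ``Delta^2`` is the second difference on the sample index, and the
weights are re-assigned each iteration as ``w_i = p`` where the signal sits
above the current baseline (points suspected to belong to peaks) and
``1 - p`` below it.  With small ``p`` (default 0.01) peaks barely pull the
baseline up, so ``z`` hugs the peak-free envelope; ``lambda`` sets the
stiffness.  Second differences are taken on the index rather than on x,
which keeps the normal equations pentadiagonal and is insensitive to the
slight non-uniformity of vendor sampling grids.

Because the penalty acts on the sample index, the stiffness that
corresponds to one physical smoothing scale grows as the fourth power of
the sampling density.  The default therefore adapts to the trace length:
``lambda = (n / 20)**4``, i.e. an effective smoothing scale of roughly 5%
of the run, which resists bulging under even broad elution peaks while
still following slow drift.  (For a typical ~600-point export this is the
conventional 1e6.)  Pass ``lambda_smooth`` explicitly to override.

The fit is deterministic and covers the whole curve.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .model import ALSParams, BaselineModel, Curve

__all__ = ["fit_baseline_als", "subtract_baseline"]

CORRECTED_SUFFIX = " (baseline-corrected)"


def default_lambda(n: int) -> float:
    """Smoothness penalty giving an effective scale of ~5% of the trace."""
    return (n / 20.0) ** 4


def fit_baseline_als(
    curve: Curve,
    lambda_smooth: float | None = None,
    p_asymmetry: float = 0.01,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> BaselineModel:
    """Fit an asymmetric-least-squares baseline to one curve.

    Parameters
    ----------
    curve:
        The trace to fit; must have at least 3 points (second differences
        are undefined below that).
    lambda_smooth:
        Smoothness penalty; larger values give a stiffer baseline.  Default
        ``(n / 20)**4`` — the index-spaced penalty equivalent of a fixed
        physical smoothing scale (about 5% of the run).
    p_asymmetry:
        Weight on points above the baseline, in (0, 1).  Small values make
        the fit ignore peaks.
    max_iter, tol:
        Weight-reassignment iterations stop when the relative change of z
        drops below ``tol`` or after ``max_iter`` rounds.

    Returns
    -------
    BaselineModel
        Baseline values aligned 1:1 with ``curve.y``, the parameters used,
        and whether the iteration converged.
    """
    y = np.asarray(curve.y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("baseline fitting needs at least 3 points")
    if lambda_smooth is None:
        lambda_smooth = default_lambda(n)
    params = ALSParams(lambda_smooth, p_asymmetry, max_iter, tol)

    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
    )
    penalty = (lambda_smooth * (d2.T @ d2)).tocsc()
    w = np.ones(n)
    z = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lhs = sparse.diags_array(w).tocsc() + penalty
        z_new = spsolve(lhs, w * y)
        if z is not None:
            denom = np.linalg.norm(z)
            change = np.linalg.norm(z_new - z) / (denom if denom > 0 else 1.0)
            if change < tol:
                z = z_new
                converged = True
                break
        z = z_new
        w = np.where(y > z, p_asymmetry, 1.0 - p_asymmetry)
    return BaselineModel(
        curve_name=curve.name, z=z, params=params, converged=converged, n_iter=n_iter
    )


def subtract_baseline(curve: Curve, model: BaselineModel) -> Curve:
    """Return the baseline-corrected curve (``y - z``).

    The model must have been fitted to this curve: names and lengths must
    match.  The returned curve's name carries a ``(baseline-corrected)``
    suffix.
    """
    if model.curve_name != curve.name:
        raise ValueError(
            f"baseline was fitted to {model.curve_name!r}, not {curve.name!r}"
        )
    if len(model.z) != len(curve):
        raise ValueError(
            f"baseline length {len(model.z)} does not match curve length {len(curve)}"
        )
    return curve.replace_y(curve.y - model.z, name=curve.name + CORRECTED_SUFFIX)
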