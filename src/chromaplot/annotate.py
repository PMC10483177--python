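"""Normalisation, range restriction, peak-area integration and zoom.

These operations sit between parsing and rendering: they produce the
restricted/derived views the plot layers draw, and the area-under-curve
numbers used to quantify how much material eluted in a fraction.

The curve between samples is treated as piecewise linear (the trapezoidal
convention), so restricting to a volume range inserts exact interpolated
boundary points and areas are additive over adjacent intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, EmptySelectionError
from .model import (
    BaselineModel,
    Chromatogram,
    Curve,
    FractionInterval,
    Selection,
)

__all__ = [
    "normalize_curve",
    "restrict_to_range",
    "integrate_auc",
    "apply_zoom",
    "ZoomView",
]

NORMALIZATION_METHODS = ("none", "shift_min_zero", "minmax_01")


def normalize_curve(curve: Curve, method: str = "shift_min_zero") -> Curve:
    """Normalise a curve's signal values; x is untouched.

    ``shift_min_zero`` (the default used for automatic plotting) subtracts
    the minimum so the trace starts at zero but keeps mAU units readable;
    ``minmax_01`` rescales to [0, 1] for overlaying channels of very
    different magnitude; ``none`` is the identity.  Both methods are
    idempotent.  ``minmax_01`` on a constant curve is undefined and raises
    :class:`DegenerateInputError`.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization {method!r}; choose from {NORMALIZATION_METHODS}"
        )
    if method == "none":
        return curve
    lo = float(np.min(curve.y))
    if method == "shift_min_zero":
        return curve.replace_y(curve.y - lo)
    hi = float(np.max(curve.y))
    if hi == lo:
        raise DegenerateInputError(
            f"curve {curve.name!r} is constant; min-max scaling is undefined"
        )
    return curve.replace_y((curve.y - lo) / (hi - lo))


def restrict_to_range(curve: Curve, vmin: float, vmax: float) -> Curve:
    """Samples of ``curve`` with vmin <= x <= vmax, plus linearly
    interpolated boundary points at exactly vmin and vmax.

    The inserted boundary points make a filled area start and stop at the
    requested volumes rather than at the nearest samples.  The range must
    overlap the curve's extent with positive width, else
    :class:`EmptySelectionError`.
    """
    if not vmin < vmax:
        raise ValueError(f"need vmin < vmax, got {vmin}, {vmax}")
    x, y = curve.x, curve.y
    lo = max(vmin, float(x[0]))
    hi = min(vmax, float(x[-1]))
    if lo >= hi:
        raise EmptySelectionError(
            f"range ({vmin}, {vmax}) does not overlap the curve extent "
            f"[{x[0]}, {x[-1]}]"
        )
    mask = (x >= lo) & (x <= hi)
    xs = list(x[mask])
    ys = list(y[mask])
    if not xs or xs[0] > lo:
        xs.insert(0, lo)
        ys.insert(0, float(np.interp(lo, x, y)))
    if xs[-1] < hi:
        xs.append(hi)
        ys.append(float(np.interp(hi, x, y)))
    return Curve(
        name=curve.name,
        x=xs,
        y=ys,
        x_unit=curve.x_unit,
        y_unit=curve.y_unit,
        wavelength_nm=curve.wavelength_nm,
    )


def _interval_bounds(interval) -> tuple[float, float]:
    if isinstance(interval, FractionInterval):
        return interval.start_ml, interval.end_ml
    lo, hi = interval
    return float(lo), float(hi)


def integrate_auc(
    curve: Curve, interval, baseline: BaselineModel | None = None
) -> float:
    """Trapezoidal area under the curve over a volume interval (ml x mAU).

    ``interval`` is a :class:`FractionInterval` or a ``(start, end)`` pair.
    If a fitted ``baseline`` is given, its values (interpolated onto the
    restricted grid) are subtracted first, so the result can be negative
    where the signal dips below the baseline.  Areas are additive over
    adjacent intervals.
    """
    lo, hi = _interval_bounds(interval)
    seg = restrict_to_range(curve, lo, hi)
    y = seg.y
    if baseline is not None:
        if len(baseline.z) != len(curve):
            raise ValueError("baseline is not aligned with this curve")
        y = y - np.interp(seg.x, curve.x, baseline.z)
    return float(np.trapezoid(y, seg.x))


@dataclass
class ZoomView:
    """Everything a renderer needs, clipped to one zoom window."""

    window: tuple[float, float]
    y_window: tuple[float, float] | None
    curves: list[Curve]
    baselines: dict[str, np.ndarray] = field(default_factory=dict)
    intervals: list[FractionInterval] = field(default_factory=list)
    volume_range: tuple[float, float] | None = None


def apply_zoom(
    selection: Selection,
    chrom: Chromatogram,
    baselines: dict[str, BaselineModel] | None = None,
) -> ZoomView:
    """Clip curves, baselines, fraction intervals and highlights to the
    selection's zoom window.

    Without a zoom the full extent is used and every view is the identity.
    Fraction intervals partially inside the window are truncated to it;
    intervals fully outside are dropped.  Because clipping only inserts
    interpolated boundary points, the area of any sub-interval inside the
    window is unchanged by zooming.  A window that excludes all data raises
    :class:`EmptySelectionError`.
    """
    selection.validate_against(chrom)
    x_lo = min(float(c.x[0]) for c in chrom.curves)
    x_hi = max(float(c.x[-1]) for c in chrom.curves)
    if selection.zoom is None:
        xmin, xmax = x_lo, x_hi
        y_window = None
    else:
        z = selection.zoom
        xmin, xmax = float(z[0]), float(z[1])
        y_window = (float(z[2]), float(z[3])) if len(z) == 4 else None
    if xmax <= x_lo or xmin >= x_hi:
        raise EmptySelectionError(
            f"zoom window ({xmin}, {xmax}) excludes all data ([{x_lo}, {x_hi}])"
        )

    curves = []
    clipped_baselines: dict[str, np.ndarray] = {}
    for c in chrom.curves:
        try:
            seg = restrict_to_range(c, xmin, xmax)
        except EmptySelectionError:
            continue
        curves.append(seg)
        if baselines and c.name in baselines:
            clipped_baselines[c.name] = np.interp(seg.x, c.x, baselines[c.name].z)
    if not curves:
        raise EmptySelectionError("zoom window excludes all curves")

    intervals: list[FractionInterval] = []
    if chrom.fraction_events:
        for iv in chrom.intervals():
            lo = max(iv.start_ml, xmin)
            hi = min(iv.end_ml, xmax)
            if lo < hi:
                intervals.append(FractionInterval(iv.label, lo, hi))

    vol_range = None
    if selection.volume_range is not None:
        lo = max(selection.volume_range[0], xmin)
        hi = min(selection.volume_range[1], xmax)
        if lo < hi:
            vol_range = (lo, hi)

    return ZoomView(
        window=(xmin, xmax),
        y_window=y_window,
        curves=curves,
        baselines=clipped_baselines,
        intervals=intervals,
        volume_range=vol_range,
    )
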