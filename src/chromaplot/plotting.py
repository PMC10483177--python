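"""Render chromatograms to matplotlib figures and export them.

The renderer is a decision tree: every style flag contributes exactly its
own layer(s) and nothing else, so the figure produced with all flags off is
the minimal two-curve plot and each feature can be toggled independently.
Layers are drawn in a fixed order (fills, curves, baselines, fraction
highlights, volume-range highlight, fraction label strip, axis labels) and
each artist is tagged with a ``gid`` such as ``curve:UV 1_280`` or
``fraction-highlight:12`` — :func:`layer_inventory` lists them, which makes
the decision tree testable without pixel comparisons.

Rendering is deterministic: the same chromatogram, style and selection give
the same layer inventory and identical raster bytes.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .annotate import apply_zoom, normalize_curve
from .model import BaselineModel, Chromatogram, PlotStyle, Selection

__all__ = ["render", "export_figure", "layer_inventory", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("pdf", "eps", "tiff", "png")

# labels closer than this fraction of the window width alternate between
# two rows in the margin strip instead of overlapping
_LABEL_COLLISION_FRAC = 0.04
_STRIP_ROW_Y = (-0.12, -0.19)  # axes-fraction y for the two label rows


def _normalized_chromatogram(chrom, method):
    curves = [normalize_curve(c, method) for c in chrom.curves]
    offsets = {}
    scales = {}
    for orig, norm in zip(chrom.curves, curves):
        lo = float(np.min(orig.y))
        offsets[orig.name] = lo
        if method == "minmax_01":
            scales[orig.name] = float(np.max(orig.y)) - lo
        else:
            scales[orig.name] = 1.0
    from dataclasses import replace

    new = replace(chrom, curves=curves)
    return new, offsets, scales


def render(
    chrom: Chromatogram,
    style: PlotStyle | None = None,
    selection: Selection | None = None,
    baselines: dict[str, BaselineModel] | None = None,
):
    """Draw a chromatogram and return the matplotlib Figure.

    Curves are normalised per ``style.normalization`` (each channel
    independently); a fitted baseline, passed via ``baselines`` keyed by
    curve name, is drawn dashed in the same color as its curve when
    ``style.show_baseline`` is on, and is transformed with the same
    normalisation so it overlays the plotted trace.  Selected fractions and
    the volume range are filled under the primary curve with translucent
    colors, so overlaps remain visible by alpha compositing.  Unknown
    fraction labels raise ``KeyError`` listing the available ones.
    """
    style = style or PlotStyle()
    selection = selection or Selection()
    selection.validate_against(chrom)

    norm_chrom, offsets, scales = _normalized_chromatogram(chrom, style.normalization)
    # baselines follow the same per-curve transform as their curve
    norm_baselines = {}
    if baselines:
        for name, model in baselines.items():
            base_name = name
            if base_name not in offsets:
                raise KeyError(
                    f"baseline refers to unknown curve {name!r}; "
                    f"available: {chrom.curve_names}"
                )
            z = (model.z - offsets[base_name]) / scales[base_name]
            norm_baselines[name] = BaselineModel(
                curve_name=name,
                z=z,
                params=model.params,
                converged=model.converged,
                n_iter=model.n_iter,
            )

    view = apply_zoom(selection, norm_chrom, norm_baselines or None)

    fig, ax = plt.subplots(figsize=(8, 5))
    primary_name = chrom.primary_curve().name
    primary_view = next(
        (c for c in view.curves if c.name == primary_name), view.curves[0]
    )

    # 1. optional fill under every curve
    if style.fill_under_curve:
        for c in view.curves:
            poly = ax.fill_between(c.x, c.y, 0.0, color=style.fill_color, zorder=1)
            poly.set_gid(f"fill:{c.name}")

    # 2. the curves themselves
    for i, c in enumerate(view.curves):
        (line,) = ax.plot(
            c.x, c.y, color=style.color_for(chrom.curve(c.name), i), zorder=3, lw=1.2
        )
        line.set_gid(f"curve:{c.name}")
        line.set_label(c.name)

    # 3. optional baselines, same color as their curve, dashed
    if style.show_baseline:
        for i, c in enumerate(view.curves):
            if c.name not in view.baselines:
                continue
            (bl,) = ax.plot(
                c.x,
                view.baselines[c.name],
                color=style.color_for(chrom.curve(c.name), i),
                ls="--",
                lw=1.0,
                zorder=2,
            )
            bl.set_gid(f"baseline:{c.name}")

    # 4. selected fraction areas and volume-range area (alpha-composited)
    selected = set(selection.selected_fraction_labels)
    if selected:
        for iv in view.intervals:
            if iv.label not in selected:
                continue
            seg_mask = (primary_view.x >= iv.start_ml) & (primary_view.x <= iv.end_ml)
            xs = primary_view.x[seg_mask]
            ys = primary_view.y[seg_mask]
            xs, ys = _with_edges(primary_view, iv.start_ml, iv.end_ml, xs, ys)
            poly = ax.fill_between(
                xs,
                ys,
                0.0,
                color=style.fraction_highlight_color,
                alpha=style.fraction_highlight_alpha,
                zorder=4,
                linewidth=0,
            )
            poly.set_gid(f"fraction-highlight:{iv.label}")
    if view.volume_range is not None:
        lo, hi = view.volume_range
        mask = (primary_view.x >= lo) & (primary_view.x <= hi)
        xs, ys = _with_edges(primary_view, lo, hi, primary_view.x[mask], primary_view.y[mask])
        poly = ax.fill_between(
            xs,
            ys,
            0.0,
            color=style.volume_highlight_color,
            alpha=style.volume_highlight_alpha,
            zorder=4,
            linewidth=0,
        )
        poly.set_gid("range-highlight")

    # 5. optional fraction tick marks + labels in a strip under the plot
    if style.show_fraction_labels_under_plot and view.intervals:
        _draw_fraction_strip(ax, view)

    # 6. axis labels, window, legend
    ax.set_xlabel(style.x_label)
    ax.set_ylabel(style.y_label)
    ax.set_xlim(*view.window)
    if view.y_window is not None:
        ax.set_ylim(*view.y_window)
    if len(view.curves) > 1:
        leg = ax.legend(loc="upper right", frameon=False)
        leg.set_gid("legend")
    if style.show_fraction_labels_under_plot and view.intervals:
        fig.subplots_adjust(bottom=0.22)
    return fig


def _with_edges(curve, lo, hi, xs, ys):
    """Prepend/append exact interpolated boundary points for a fill."""
    xs = list(xs)
    ys = list(ys)
    if not xs or xs[0] > lo:
        xs.insert(0, lo)
        ys.insert(0, float(np.interp(lo, curve.x, curve.y)))
    if xs[-1] < hi:
        xs.append(hi)
        ys.append(float(np.interp(hi, curve.x, curve.y)))
    return np.asarray(xs), np.asarray(ys)


def _draw_fraction_strip(ax, view) -> None:
    """Tick at each visible interval start with its label beneath the axis.

    When neighbouring starts sit closer than a few percent of the window
    width the labels alternate between two rows, preventing the overlaps
    that would otherwise need manual cleanup in an image editor.
    """
    xmin, xmax = view.window
    min_gap = _LABEL_COLLISION_FRAC * (xmax - xmin)
    starts = [iv.start_ml for iv in view.intervals]
    crowded = any(b - a < min_gap for a, b in zip(starts, starts[1:]))
    trans = ax.get_xaxis_transform()  # x in data coords, y in axes coords
    for i, iv in enumerate(view.intervals):
        row = i % 2 if crowded else 0
        (tick,) = ax.plot(
            [iv.start_ml, iv.start_ml],
            [0.0, -0.03 - 0.04 * row],
            transform=trans,
            color="black",
            lw=0.8,
            clip_on=False,
        )
        tick.set_gid(f"fraction-strip-tick:{iv.label}")
        txt = ax.text(
            iv.start_ml,
            _STRIP_ROW_Y[row],
            iv.label,
            transform=trans,
            ha="center",
            va="top",
            fontsize=8,
            clip_on=False,
        )
        txt.set_gid(f"fraction-strip-label:{iv.label}")


def layer_inventory(fig) -> list[str]:
    """Sorted gid tags of every tagged artist in the figure.

    This is the introspectable form of the renderer's decision tree: each
    enabled feature contributes its documented tags and nothing else.
    """
    tags = []
    seen = set()

    def walk(artist):
        if id(artist) in seen:
            return
        seen.add(id(artist))
        gid = artist.get_gid()
        if gid:
            tags.append(gid)
        for child in artist.get_children():
            walk(child)

    walk(fig)
    return sorted(tags)


def export_figure(
    fig,
    path,
    format: str | None = None,
    dpi: int = 300,
    size_inches: tuple[float, float] | None = None,
) -> Path:
    """Save a figure as PDF/EPS (vector) or TIFF/PNG (raster).

    ``format`` defaults to the path suffix.  Raster outputs have pixel
    dimensions ``round(size_inches * dpi)``.  The file is written to a
    temporary name and atomically renamed, so a failed export leaves no
    partial file.  PDF metadata omits the creation date so repeated exports
    are byte-identical.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = {"tif": "tiff"}.get(format, format)
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; supported formats: "
            + ", ".join(SUPPORTED_FORMATS)
        )
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    if size_inches is not None:
        fig.set_size_inches(*size_inches)

    kwargs: dict = {"format": format, "dpi": dpi}
    if format == "pdf":
        kwargs["metadata"] = {"CreationDate": None}
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=f".{format}.part")
    try:
        os.close(fd)
        fig.savefig(tmp, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path
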