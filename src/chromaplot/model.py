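"""Domain model for preparative liquid-chromatography runs.

A :class:`Chromatogram` is one purification run as recorded by the
instrument: one or more detector traces (:class:`Curve`, signal in mAU
against elution volume in ml), the fraction-collector marks
(:class:`FractionEvent`), plus injection and logbook events.  These types
are pure data with validation — no I/O and no plotting lives here.

Volumes are a continuous axis in ml.  Time-based exports are accepted too;
the axis label simply follows the unit row of the source file.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundaryError

__all__ = [
    "Curve",
    "FractionEvent",
    "FractionInterval",
    "Chromatogram",
    "ALSParams",
    "BaselineModel",
    "PlotStyle",
    "Selection",
    "fraction_intervals",
    "wavelength_from_name",
    "curves_equal",
    "chromatograms_equal",
]

# Wavelengths commonly exported by UV detectors on FPLC systems.
RECOGNIZED_WAVELENGTHS = (230, 260, 280)

#: Default trace colors: 260 nm (nucleic acids) red, 280 nm (protein) blue.
DEFAULT_WAVELENGTH_COLORS = {260: "red", 280: "blue", 230: "green"}

_FALLBACK_COLORS = ("black", "dimgray", "darkorange", "teal", "brown", "magenta")


def wavelength_from_name(name: str) -> int | None:
    """Extract a detector wavelength (nm) from a curve name.

    Unicorn names UV traces like ``"UV 1_280"`` — the trailing integer after
    the last underscore is the wavelength.  Failing that, an embedded
    230/260/280 token is recognized.  Returns ``None`` when no wavelength
    can be identified; never raises.
    """
    if not name:
        return None
    tail = name.rsplit("_", 1)
    if len(tail) == 2:
        m = re.fullmatch(r"(\d+)", tail[1].strip())
        if m:
            val = int(m.group(1))
            if val > 0:
                return val
    for wl in RECOGNIZED_WAVELENGTHS:
        if re.search(rf"(?<!\d){wl}(?!\d)", name):
            return wl
    return None


def _as_float_array(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Curve:
    """One detector trace: signal values over elution volume.

    Parameters
    ----------
    name:
        Channel name as exported, e.g. ``"UV 1_280"``.
    x, y:
        Elution volumes (ml) and signal values (mAU or other unit).  Must
        have equal length >= 2, be finite, with ``x`` nondecreasing.
    x_unit, y_unit:
        Axis unit labels, taken from the file's unit row.
    wavelength_nm:
        Detector wavelength; parsed from the name when not given.
    """

    name: str
    x: np.ndarray
    y: np.ndarray
    x_unit: str = "ml"
    y_unit: str = "mAU"
    wavelength_nm: int | None = None

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        if len(self.x) != len(self.y):
            raise ValueError(
                f"curve {self.name!r}: x and y lengths differ "
                f"({len(self.x)} vs {len(self.y)})"
            )
        if len(self.x) < 2:
            raise ValueError(f"curve {self.name!r}: needs at least 2 points")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise ValueError(f"curve {self.name!r}: values must be finite")
        dx = np.diff(self.x)
        if np.any(dx < 0):
            raise ValueError(f"curve {self.name!r}: x must be nondecreasing")
        if np.any(dx == 0):
            warnings.warn(
                f"curve {self.name!r} contains duplicate x values; kept as-is",
                stacklevel=2,
            )
        if self.wavelength_nm is None:
            self.wavelength_nm = wavelength_from_name(self.name)
        elif self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")

    def __len__(self) -> int:
        return len(self.x)

    def replace_y(self, y, name: str | None = None, y_unit: str | None = None) -> "Curve":
        """New curve with the same x grid and different signal values."""
        return Curve(
            name=self.name if name is None else name,
            x=self.x.copy(),
            y=y,
            x_unit=self.x_unit,
            y_unit=self.y_unit if y_unit is None else y_unit,
            wavelength_nm=self.wavelength_nm,
        )


@dataclass(frozen=True)
class FractionEvent:
    """A fraction-collector mark: the volume at which a fraction starts."""

    start_ml: float
    label: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.start_ml):
            raise ValueError("fraction start volume must be finite")
        if not self.label:
            raise ValueError("fraction label must be nonempty")


@dataclass(frozen=True)
class FractionInterval:
    """The volume interval a collected fraction spans."""

    label: str
    start_ml: float
    end_ml: float

    def __post_init__(self) -> None:
        if not (self.start_ml < self.end_ml):
            raise BoundaryError(
                f"fraction {self.label!r}: start {self.start_ml} must be "
                f"< end {self.end_ml}"
            )

    @property
    def width_ml(self) -> float:
        return self.end_ml - self.start_ml


def fraction_intervals(
    events: list[FractionEvent], x_end: float
) -> list[FractionInterval]:
    """Convert fraction start marks into contiguous volume intervals.

    Each fraction spans from its own start to the next fraction's start;
    the last one ends at ``x_end`` (conventionally the maximum elution
    volume of the primary UV trace, i.e. as far as a filled area can
    visually extend).  The intervals tile ``[first_start, x_end]`` with no
    gaps or overlaps.

    An empty event list yields an empty result.  ``x_end`` at or before the
    last start would create a zero/negative-width interval and raises
    :class:`BoundaryError`.
    """
    if not events:
        return []
    starts = [e.start_ml for e in events]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise BoundaryError("fraction events must have strictly increasing starts")
    if x_end <= starts[-1]:
        raise BoundaryError(
            f"x_end ({x_end}) must lie beyond the last fraction start "
            f"({starts[-1]})"
        )
    edges = starts + [x_end]
    return [
        FractionInterval(label=e.label, start_ml=lo, end_ml=hi)
        for e, lo, hi in zip(events, edges[:-1], edges[1:])
    ]


@dataclass
class ChromatogramMeta:
    """Provenance of a parsed run."""

    source: str = ""
    dialect: object | None = None  # DialectDescriptor; untyped to avoid an import cycle
    chrom_id: str = "Chrom.1"
    warnings: list[str] = field(default_factory=list)


@dataclass
class Chromatogram:
    """A parsed chromatography run: curves plus collector/injection events."""

    curves: list[Curve]
    fraction_events: list[FractionEvent] = field(default_factory=list)
    injection_events: list[tuple[float, str]] = field(default_factory=list)
    logbook: list[tuple[float, str]] = field(default_factory=list)
    meta: ChromatogramMeta = field(default_factory=ChromatogramMeta)

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("a chromatogram needs at least one curve")
        names = [c.name for c in self.curves]
        if len(set(names)) != len(names):
            raise ValueError(f"curve names must be unique, got {names}")
        starts = [e.start_ml for e in self.fraction_events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("fraction event volumes must be strictly increasing")
        labels = [e.label for e in self.fraction_events]
        if len(set(labels)) != len(labels):
            raise ValueError("fraction labels must be unique")
        for vol, _ in list(self.injection_events) + list(self.logbook):
            if not np.isfinite(vol):
                raise ValueError("event volumes must be finite")

    @property
    def curve_names(self) -> list[str]:
        return [c.name for c in self.curves]

    @property
    def fraction_labels(self) -> list[str]:
        return [e.label for e in self.fraction_events]

    def curve(self, name: str) -> Curve:
        for c in self.curves:
            if c.name == name:
                return c
        raise KeyError(f"no curve named {name!r}; available: {self.curve_names}")

    def primary_curve(self) -> Curve:
        """The trace annotations attach to: the 280 nm trace if present,
        else the first UV trace, else the first curve."""
        for c in self.curves:
            if c.wavelength_nm == 280:
                return c
        for c in self.curves:
            if c.wavelength_nm is not None:
                return c
        return self.curves[0]

    def intervals(self, x_end: float | None = None) -> list[FractionInterval]:
        """Fraction intervals; the last ends at the primary curve's max x
        unless ``x_end`` overrides it."""
        if x_end is None:
            x_end = float(self.primary_curve().x[-1])
        return fraction_intervals(self.fraction_events, x_end)


@dataclass(frozen=True)
class ALSParams:
    """Asymmetric-least-squares baseline parameters (see the baseline module)."""

    lambda_smooth: float = 1e6
    p_asymmetry: float = 0.01
    max_iter: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_smooth <= 0:
            raise ValueError("lambda_smooth must be positive")
        if not (0 < self.p_asymmetry < 1):
            raise ValueError("p_asymmetry must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class BaselineModel:
    """A fitted baseline aligned 1:1 with one curve's samples."""

    curve_name: str
    z: np.ndarray
    params: ALSParams
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        self.z = _as_float_array(self.z, "z")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("baseline values must be finite")


def _is_color(c: str) -> bool:
    from matplotlib.colors import is_color_like

    return is_color_like(c)


@dataclass
class PlotStyle:
    """Persisted plot styling.

    Style is what carries over from one file to the next when plotting many
    similar runs; per-file choices (which fractions, which volume range,
    zoom) live in :class:`Selection` and are never persisted.
    """

    curve_colors: dict[str, str] = field(default_factory=dict)
    fill_under_curve: bool = False
    fill_color: str = "lightgray"
    fraction_highlight_color: str = "purple"
    fraction_highlight_alpha: float = 0.4
    volume_highlight_color: str = "gold"
    volume_highlight_alpha: float = 0.3
    show_baseline: bool = False
    show_fraction_labels_under_plot: bool = False
    x_label: str = "Elution volume (ml)"
    y_label: str = "mAU"
    normalization: str = "shift_min_zero"

    def __post_init__(self) -> None:
        for key, col in [
            ("fill_color", self.fill_color),
            ("fraction_highlight_color", self.fraction_highlight_color),
            ("volume_highlight_color", self.volume_highlight_color),
            *[(f"curve_colors[{k!r}]", v) for k, v in self.curve_colors.items()],
        ]:
            if not _is_color(col):
                raise ValueError(f"{key}: {col!r} is not a valid color")
        for key, a in [
            ("fraction_highlight_alpha", self.fraction_highlight_alpha),
            ("volume_highlight_alpha", self.volume_highlight_alpha),
        ]:
            if not (0 < a <= 1):
                raise ValueError(f"{key} must lie in (0, 1], got {a}")
        if self.normalization not in ("none", "shift_min_zero", "minmax_01"):
            raise ValueError(
                "normalization must be one of 'none', 'shift_min_zero', "
                f"'minmax_01'; got {self.normalization!r}"
            )

    def color_for(self, curve: Curve, index: int = 0) -> str:
        """Resolve a curve's color: explicit override, else the wavelength
        default (260 red / 280 blue), else a deterministic fallback."""
        if curve.name in self.curve_colors:
            return self.curve_colors[curve.name]
        if curve.wavelength_nm in DEFAULT_WAVELENGTH_COLORS:
            return DEFAULT_WAVELENGTH_COLORS[curve.wavelength_nm]
        return _FALLBACK_COLORS[index % len(_FALLBACK_COLORS)]


@dataclass
class Selection:
    """Per-file selections: chosen fractions, highlighted volume range, zoom.

    Unlike :class:`PlotStyle`, a Selection refers to labels and volumes of
    one specific file and is restated for every new file.
    """

    selected_fraction_labels: list[str] = field(default_factory=list)
    volume_range: tuple[float, float] | None = None
    zoom: tuple | None = None  # (xmin, xmax) or (xmin, xmax, ymin, ymax)

    def __post_init__(self) -> None:
        if self.volume_range is not None:
            vmin, vmax = self.volume_range
            if not vmin < vmax:
                raise ValueError(f"volume_range: need vmin < vmax, got {vmin}, {vmax}")
        if self.zoom is not None:
            z = tuple(self.zoom)
            if len(z) not in (2, 4):
                raise ValueError("zoom must be (xmin, xmax) or (xmin, xmax, ymin, ymax)")
            if not z[0] < z[1]:
                raise ValueError(f"zoom: need xmin < xmax, got {z[0]}, {z[1]}")
            if len(z) == 4 and not z[2] < z[3]:
                raise ValueError(f"zoom: need ymin < ymax, got {z[2]}, {z[3]}")
            self.zoom = z

    def validate_against(self, chrom: Chromatogram) -> None:
        """Check that all selected fraction labels exist in the run."""
        available = set(chrom.fraction_labels)
        missing = [l for l in self.selected_fraction_labels if l not in available]
        if missing:
            raise KeyError(
                f"unknown fraction label(s) {missing}; "
                f"available: {chrom.fraction_labels}"
            )


def curves_equal(a: Curve, b: Curve, rtol: float = 0.0, atol: float = 0.0) -> bool:
    """Field-wise curve equality (exact by default)."""
    return (
        a.name == b.name
        and a.x_unit == b.x_unit
        and a.y_unit == b.y_unit
        and len(a) == len(b)
        and np.allclose(a.x, b.x, rtol=rtol, atol=atol)
        and np.allclose(a.y, b.y, rtol=rtol, atol=atol)
    )


def chromatograms_equal(
    a: Chromatogram, b: Chromatogram, rtol: float = 0.0, atol: float = 0.0
) -> bool:
    """Field-wise equality of two runs, ignoring provenance metadata."""
    if len(a.curves) != len(b.curves):
        return False
    if not all(curves_equal(ca, cb, rtol, atol) for ca, cb in zip(a.curves, b.curves)):
        return False
    if len(a.fraction_events) != len(b.fraction_events):
        return False
    for ea, eb in zip(a.fraction_events, b.fraction_events):
        if ea.label != eb.label or not np.isclose(
            ea.start_ml, eb.start_ml, rtol=rtol, atol=atol
        ):
            return False
    for evs_a, evs_b in [
        (a.injection_events, b.injection_events),
        (a.logbook, b.logbook),
    ]:
        if len(evs_a) != len(evs_b):
            return False
        for (va, ta), (vb, tb) in zip(evs_a, evs_b):
            if ta != tb or not np.isclose(va, vb, rtol=rtol, atol=atol):
                return False
    return True
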