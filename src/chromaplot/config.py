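"""Style configuration files.

A style config is a flat, diff-friendly YAML file holding exactly the
fields of :class:`~chromaplot.model.PlotStyle` — what carries over when the
same look is applied to many runs.  Per-file selections (which fractions,
which volume range, zoom) are deliberately *not* persistable: a config
containing such keys is rejected, because fraction labels and volumes are
meaningless outside the file they came from and must be restated per run.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import PlotStyle

__all__ = ["save_style", "load_style", "STYLE_KEYS", "FORBIDDEN_SELECTION_KEYS"]

STYLE_KEYS = tuple(f.name for f in fields(PlotStyle))

#: selection concepts that must never appear in a persisted style
FORBIDDEN_SELECTION_KEYS = (
    "fractions",
    "selected_fraction_labels",
    "selected_fractions",
    "range",
    "volume_range",
    "zoom",
)


def save_style(style: PlotStyle, path) -> None:
    """Write a style to a YAML config file (keys sorted, one per line)."""
    data = {}
    for f in fields(PlotStyle):
        data[f.name] = getattr(style, f.name)
    text = yaml.safe_dump(data, sort_keys=True, default_flow_style=False)
    Path(path).write_text(text, encoding="utf-8")


def load_style(path) -> PlotStyle:
    """Load a style config, rejecting unknown and selection-like keys.

    Missing keys fall back to the defaults, so configs remain readable
    across versions; unknown keys are an error (listed, never silently
    ignored), and selection keys are refused with an explanation.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse style config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"style config {path} must be a mapping of keys to values")

    forbidden = sorted(k for k in raw if k in FORBIDDEN_SELECTION_KEYS)
    if forbidden:
        raise ConfigError(
            f"style config contains per-file selection key(s) {forbidden}: "
            "fraction choices, volume ranges and zoom refer to one specific "
            "file and are never persisted — restate them per run"
        )
    unknown = sorted(k for k in raw if k not in STYLE_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown style config key(s) {unknown}; valid keys: "
            + ", ".join(STYLE_KEYS)
        )
    if "zoom" in raw:  # unreachable (forbidden above) but kept for clarity
        raise ConfigError("zoom is a per-file selection")
    try:
        return PlotStyle(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid style config value: {exc}") from exc
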