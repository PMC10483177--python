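"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ChromaplotError`, so callers (and the CLI) can catch one type.
"""


class ChromaplotError(Exception):
    """Base class for all chromaplot errors."""


class FormatError(ChromaplotError, ValueError):
    """A file does not conform to the expected dialect/layout."""


class BoundaryError(ChromaplotError, ValueError):
    """An interval or range boundary is degenerate or out of order."""


class EmptySelectionError(ChromaplotError, ValueError):
    """A volume range or zoom window selects no data."""


class DegenerateInputError(ChromaplotError, ValueError):
    """An operation is undefined on this input (e.g. min-max scaling a flat trace)."""


class ConfigError(ChromaplotError, ValueError):
    """A style configuration file is malformed or contains forbidden keys."""
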