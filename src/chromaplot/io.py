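"""Readers and writers for chromatography ASCII exports.

Two layouts are supported:

**Unicorn paired-column export** (``.txt`` or ``.csv``).  Every recorded
series — curve, fraction marks, injections, logbook — owns an adjacent pair
of columns (volume, value).  Row 1 carries the series name in the first
column of each pair; row 2 carries the units.  Series may have different
lengths, so data columns are ragged: short columns are padded with empty
trailing cells.  Files may be UTF-16 (BOM-prefixed), tab/semicolon/comma
delimited, with ``.`` or ``,`` as the decimal mark — see
:class:`DialectDescriptor` and :func:`detect_dialect`.  Header conventions
vary between instrument-software versions; rather than editing parser code
per version, tolerance is expressed as an overridable descriptor object.

**Generic template** for non-Unicorn instruments: tab-separated, row 1
names, row 2 units, a single shared volume column followed by one y column
per curve, plus an optional trailing (volume, label) fraction pair.  A
blank copy is emitted by :func:`blank_template` / ``chromaplot template``.

Numbers are written with :func:`repr` (shortest exact representation), so a
write→parse round trip reproduces every value bit-for-bit.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import FormatError
from .model import (
    Chromatogram,
    ChromatogramMeta,
    Curve,
    FractionEvent,
)

__all__ = [
    "DialectDescriptor",
    "detect_dialect",
    "parse_unicorn_txt",
    "parse_unicorn_csv",
    "parse_template",
    "write_unicorn_txt",
    "write_template",
    "blank_template",
    "all_dialects",
]

_DELIMS = {"tab": "\t", "comma": ",", "semicolon": ";"}
_ENCODINGS = ("utf-8", "utf-16-le", "utf-16-be", "latin-1")

# unit-row tokens that mark event (non-curve) column pairs
_FRACTION_TOKEN = "fraction"
_INJECTION_TOKEN = "injection"
_LOGBOOK_TOKEN = "logbook"


@dataclass(frozen=True)
class DialectDescriptor:
    """How one export file is encoded on disk.

    ``delimiter`` and ``decimal_mark`` must differ (a comma cannot serve as
    both); ``column_pairing`` flags the paired (x, y) column layout of the
    Unicorn export as opposed to the shared-x template.
    """

    encoding: str = "utf-8"
    delimiter: str = "tab"
    decimal_mark: str = "."
    n_header_rows: int = 2
    column_pairing: bool = True

    def __post_init__(self) -> None:
        if self.encoding not in _ENCODINGS:
            raise ValueError(f"encoding must be one of {_ENCODINGS}")
        if self.delimiter not in _DELIMS:
            raise ValueError(f"delimiter must be one of {tuple(_DELIMS)}")
        if self.decimal_mark not in (".", ","):
            raise ValueError("decimal_mark must be '.' or ','")
        if self.delimiter == "comma" and self.decimal_mark == ",":
            raise ValueError("delimiter and decimal mark cannot both be ','")
        if self.n_header_rows < 2:
            raise ValueError("need at least a name row and a unit row")

    @property
    def delimiter_char(self) -> str:
        return _DELIMS[self.delimiter]


def all_dialects() -> list[DialectDescriptor]:
    """Every supported (encoding, delimiter, decimal) combination — 20 total."""
    out = []
    for enc in _ENCODINGS:
        for delim in _DELIMS:
            for dec in (".", ","):
                if delim == "comma" and dec == ",":
                    continue
                out.append(
                    DialectDescriptor(encoding=enc, delimiter=delim, decimal_mark=dec)
                )
    return out


# ---------------------------------------------------------------------------
# byte-level helpers


def _read_bytes(source) -> bytes:
    """Accept a path, bytes, or a binary file-like object."""
    if isinstance(source, bytes):
        return source
    if isinstance(source, (str, Path)):
        return Path(source).read_bytes()
    data = source.read()
    if isinstance(data, str):
        return data.encode("utf-8")
    return data


def _source_name(source) -> str:
    if isinstance(source, (str, Path)):
        return str(source)
    return getattr(source, "name", "") or ""


_NUM_DOT = re.compile(r"^-?\d+\.\d+(?:[eE][+-]?\d+)?$")
_NUM_COMMA = re.compile(r"^-?\d+,\d+(?:[eE][+-]?\d+)?$")


def detect_dialect(data: bytes) -> DialectDescriptor:
    """Infer encoding, delimiter and decimal mark from raw bytes.

    Encoding comes from the BOM (UTF-16) or a UTF-8/latin-1 decode attempt;
    the delimiter from its frequency in the header row; the decimal mark
    from sampling numeric data cells.  Deterministic for a fixed stream.
    """
    data = _read_bytes(data)
    if not data:
        raise FormatError("empty stream")
    if data.startswith(b"\xff\xfe"):
        encoding, body = "utf-16-le", data[2:]
    elif data.startswith(b"\xfe\xff"):
        encoding, body = "utf-16-be", data[2:]
    else:
        body = data[3:] if data.startswith(b"\xef\xbb\xbf") else data
        try:
            body.decode("utf-8")
            encoding = "utf-8"
        except UnicodeDecodeError:
            encoding = "latin-1"
    try:
        text = body.decode(encoding)
    except UnicodeDecodeError as exc:
        raise FormatError(
            f"undecodable bytes for {encoding} at offset {exc.start}"
        ) from exc

    lines = text.splitlines()
    if not lines:
        raise FormatError("stream contains no lines")
    header = lines[0]
    counts = {name: header.count(ch) for name, ch in _DELIMS.items()}
    # tab wins ties (it is the vendor default); comma last, since commas can
    # also appear inside free-text cells
    delimiter = max(("tab", "semicolon", "comma"), key=lambda n: counts[n])
    if counts[delimiter] == 0:
        raise FormatError("no recognizable delimiter in header row")

    decimal = "."
    if delimiter != "comma":
        dot = comma = 0
        for line in lines[1:200]:
            for cell in line.split(_DELIMS[delimiter]):
                cell = cell.strip()
                if _NUM_DOT.match(cell):
                    dot += 1
                elif _NUM_COMMA.match(cell):
                    comma += 1
        if comma > dot:
            decimal = ","
    return DialectDescriptor(encoding=encoding, delimiter=delimiter, decimal_mark=decimal)


def _decode(data: bytes, dialect: DialectDescriptor) -> str:
    boms = {"utf-16-le": b"\xff\xfe", "utf-16-be": b"\xfe\xff", "utf-8": b"\xef\xbb\xbf"}
    bom = boms.get(dialect.encoding)
    if bom and data.startswith(bom):
        data = data[len(bom) :]
    try:
        return data.decode(dialect.encoding)
    except UnicodeDecodeError as exc:
        raise FormatError(
            f"undecodable bytes for {dialect.encoding} at offset {exc.start}"
        ) from exc


def _parse_number(cell: str, dialect: DialectDescriptor, where: str) -> float:
    s = cell.strip()
    if dialect.decimal_mark == ",":
        s = s.replace(",", ".")
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"{where}: cannot parse {cell!r} as a number") from exc


def _format_number(v: float, dialect: DialectDescriptor) -> str:
    s = repr(float(v))
    if dialect.decimal_mark == ",":
        s = s.replace(".", ",")
    return s


def _is_numeric(cell: str, dialect: DialectDescriptor) -> bool:
    s = cell.strip()
    if dialect.decimal_mark == ",":
        s = s.replace(",", ".")
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Unicorn paired-column layout


def _column_cells(rows: list[list[str]], col: int, n_header: int) -> list[str]:
    """One column's data cells with trailing empties trimmed."""
    cells = [row[col] if col < len(row) else "" for row in rows[n_header:]]
    last = -1
    for i, c in enumerate(cells):
        if c.strip():
            last = i
    return [c.strip() for c in cells[: last + 1]]


def _pair_series(
    rows: list[list[str]], icol: int, n_header: int, name: str
) -> tuple[list[str], list[str]]:
    """Aligned (x, y) cell lists for the column pair starting at icol.

    Trailing empty cells end the series; an empty cell *inside* the series
    is ambiguous and rejected.
    """
    xs = [row[icol] if icol < len(row) else "" for row in rows[n_header:]]
    ys = [row[icol + 1] if icol + 1 < len(row) else "" for row in rows[n_header:]]
    last = -1
    for i in range(len(xs)):
        if xs[i].strip() or ys[i].strip():
            last = i
    xs, ys = xs[: last + 1], ys[: last + 1]
    for i, (a, b) in enumerate(zip(xs, ys)):
        if not a.strip() or not b.strip():
            raise FormatError(
                f"series {name!r}: empty cell inside data at row "
                f"{n_header + i + 1} (only trailing cells may be empty)"
            )
    return [a.strip() for a in xs], [b.strip() for b in ys]


_CHROM_PREFIX = re.compile(r"^(Chrom\.\d+)[ _:]*(.*)$")


def parse_unicorn_txt(source, dialect: DialectDescriptor | None = None) -> Chromatogram:
    """Parse a Unicorn paired-column ASCII export into a :class:`Chromatogram`.

    ``source`` may be a path, raw bytes, or a binary file object.  When
    ``dialect`` is not given it is detected with :func:`detect_dialect`.

    Column pairs are classified by the unit row of their second column:
    a cell containing ``fraction`` becomes the fraction-event list,
    ``injection``/``logbook`` become event lists, anything numeric becomes
    a :class:`~chromaplot.model.Curve`.  An unrecognized pair whose second
    column is non-numeric is kept as logbook-like events with a warning, so
    no named column is ever silently dropped.
    """
    data = _read_bytes(source)
    if dialect is None:
        dialect = detect_dialect(data)
    text = _decode(data, dialect)
    lines = [ln for ln in text.splitlines()]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) < dialect.n_header_rows + 1:
        raise FormatError(
            f"file has {len(lines)} lines; need {dialect.n_header_rows} header "
            "rows plus data"
        )
    delim = dialect.delimiter_char
    rows = [ln.split(delim) for ln in lines]
    ncols = max(len(r) for r in rows)
    if ncols < 2:
        raise FormatError("no column pairs found")

    name_row = rows[0]
    unit_row = rows[dialect.n_header_rows - 1]

    def cell(row: list[str], i: int) -> str:
        return row[i].strip() if i < len(row) else ""

    meta = ChromatogramMeta(source=_source_name(source), dialect=dialect)
    curves: list[Curve] = []
    fraction_events: list[FractionEvent] = []
    injections: list[tuple[float, str]] = []
    logbook: list[tuple[float, str]] = []
    chrom_ids_seen: list[str] = []

    for icol in range(0, ncols - 1, 2):
        name = cell(name_row, icol) or cell(name_row, icol + 1)
        x_unit = cell(unit_row, icol)
        y_unit = cell(unit_row, icol + 1)
        if not name and not x_unit and not y_unit:
            continue  # fully blank pair (padding)
        m = _CHROM_PREFIX.match(name)
        if m:
            chrom_id, name = m.group(1), m.group(2) or m.group(1)
            if chrom_id not in chrom_ids_seen:
                chrom_ids_seen.append(chrom_id)
            if chrom_id != (chrom_ids_seen[0] if chrom_ids_seen else chrom_id):
                meta.warnings.append(
                    f"skipped series {name!r} from {chrom_id}: only the first "
                    "chromatogram of a multi-run export is parsed"
                )
                continue
        xs, ys = _pair_series(rows, icol, dialect.n_header_rows, name or f"col {icol}")
        if not xs:
            meta.warnings.append(f"series {name!r} has no data rows; skipped")
            continue
        x = [_parse_number(c, dialect, f"series {name!r}") for c in xs]
        unit_l = y_unit.lower()
        if _FRACTION_TOKEN in unit_l:
            if any(b <= a for a, b in zip(x, x[1:])):
                bad = [
                    i + dialect.n_header_rows + 1
                    for i, (a, b) in enumerate(zip(x, x[1:]))
                    if b <= a
                ]
                raise FormatError(
                    f"fraction volumes are not strictly increasing at rows {bad}"
                )
            fraction_events = [FractionEvent(v, lab) for v, lab in zip(x, ys)]
        elif _INJECTION_TOKEN in unit_l:
            injections = list(zip(x, ys))
        elif _LOGBOOK_TOKEN in unit_l:
            logbook = list(zip(x, ys))
        elif all(_is_numeric(c, dialect) for c in ys):
            y = [_parse_number(c, dialect, f"series {name!r}") for c in ys]
            if len(y) < 2:
                meta.warnings.append(f"series {name!r} has fewer than 2 points; skipped")
                continue
            curves.append(Curve(name=name, x=x, y=y, x_unit=x_unit, y_unit=y_unit))
        else:
            meta.warnings.append(
                f"series {name!r} (unit {y_unit!r}) not recognized; kept as "
                "logbook-like events"
            )
            logbook.extend(zip(x, ys))

    if chrom_ids_seen:
        meta.chrom_id = chrom_ids_seen[0]
        if len(chrom_ids_seen) > 1:
            meta.warnings.append(
                f"export contains {len(chrom_ids_seen)} chromatograms; parsed "
                f"{chrom_ids_seen[0]} only"
            )
    if not curves:
        raise FormatError("no numeric curve column pairs found")
    return Chromatogram(
        curves=curves,
        fraction_events=fraction_events,
        injection_events=injections,
        logbook=logbook,
        meta=meta,
    )


def parse_unicorn_csv(source, dialect: DialectDescriptor | None = None) -> Chromatogram:
    """Parse the comma/semicolon-delimited variant of the Unicorn export.

    Identical to :func:`parse_unicorn_txt` with the delimiter constrained to
    comma or semicolon by :func:`detect_dialect`.
    """
    data = _read_bytes(source)
    if dialect is None:
        dialect = detect_dialect(data)
    if dialect.delimiter == "tab":
        raise FormatError("stream is tab-delimited; expected a comma/semicolon CSV")
    return parse_unicorn_txt(data, dialect)


def write_unicorn_txt(
    chrom: Chromatogram, target, dialect: DialectDescriptor | None = None
) -> None:
    """Write a chromatogram in the Unicorn paired-column layout.

    The emitted file re-parses to a field-wise-equal chromatogram (numbers
    are printed with full round-trip precision).  ``target`` is a path or a
    binary file object.
    """
    if dialect is None:
        dialect = DialectDescriptor()
    if not chrom.curves:
        raise ValueError("cannot write a chromatogram with zero curves")
    delim = dialect.delimiter_char

    pairs: list[tuple[str, str, str, list[str], list[str]]] = []
    for c in chrom.curves:
        pairs.append(
            (
                c.name,
                c.x_unit,
                c.y_unit,
                [_format_number(v, dialect) for v in c.x],
                [_format_number(v, dialect) for v in c.y],
            )
        )
    if chrom.fraction_events:
        pairs.append(
            (
                "Fraction",
                "ml",
                "(Fractions)",
                [_format_number(e.start_ml, dialect) for e in chrom.fraction_events],
                [e.label for e in chrom.fraction_events],
            )
        )
    if chrom.injection_events:
        pairs.append(
            (
                "Injection",
                "ml",
                "Injection",
                [_format_number(v, dialect) for v, _ in chrom.injection_events],
                [lab for _, lab in chrom.injection_events],
            )
        )
    if chrom.logbook:
        pairs.append(
            (
                "Logbook",
                "ml",
                "Logbook",
                [_format_number(v, dialect) for v, _ in chrom.logbook],
                [lab for _, lab in chrom.logbook],
            )
        )

    nrows = max(len(p[3]) for p in pairs)
    lines = [
        delim.join(x for p in pairs for x in (p[0], "")),
        delim.join(x for p in pairs for x in (p[1], p[2])),
    ]
    for i in range(nrows):
        cells = []
        for _, _, _, xs, ys in pairs:
            cells.append(xs[i] if i < len(xs) else "")
            cells.append(ys[i] if i < len(ys) else "")
        lines.append(delim.join(cells))
    _write_text("\n".join(lines) + "\n", target, dialect.encoding)


def _write_text(text: str, target, encoding: str) -> None:
    boms = {"utf-16-le": b"\xff\xfe", "utf-16-be": b"\xfe\xff"}
    data = boms.get(encoding, b"") + text.encode(encoding)
    if isinstance(target, (str, Path)):
        Path(target).write_bytes(data)
    else:
        target.write(data)


# ---------------------------------------------------------------------------
# generic shared-x template


def parse_template(source) -> Chromatogram:
    """Parse the generic non-Unicorn template (tab-separated, shared x).

    Column 1 is the elution-volume axis shared by all curves; each further
    numeric column is one curve (shorter curves end with empty trailing
    cells).  A column whose unit row contains ``fraction`` starts an
    optional (volume, label) pair of fraction columns.
    """
    data = _read_bytes(source)
    if not data:
        raise FormatError("empty stream")
    dialect = DialectDescriptor(
        encoding=detect_dialect(data).encoding, delimiter="tab", column_pairing=False
    )
    text = _decode(data, dialect)
    lines = text.splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) < 3:
        raise FormatError("template needs 2 header rows plus data")
    rows = [ln.split("\t") for ln in lines]
    ncols = max(len(r) for r in rows)
    if ncols < 2:
        raise FormatError("template needs a volume column and at least one curve")

    name_row, unit_row = rows[0], rows[1]

    def cell(row: list[str], i: int) -> str:
        return row[i].strip() if i < len(row) else ""

    x_cells = _column_cells(rows, 0, 2)
    x_unit = cell(unit_row, 0)
    x = [_parse_number(c, dialect, "volume column") for c in x_cells]

    meta = ChromatogramMeta(source=_source_name(source), dialect=dialect)
    curves: list[Curve] = []
    fraction_events: list[FractionEvent] = []
    icol = 1
    while icol < ncols:
        name = cell(name_row, icol)
        unit = cell(unit_row, icol)
        if _FRACTION_TOKEN in unit.lower() or _FRACTION_TOKEN in name.lower():
            # (volume, label) pair
            if icol + 1 >= ncols:
                raise FormatError("fraction volume column lacks its label column")
            fx, flab = _pair_series(rows, icol, 2, name or "Fraction")
            fvol = [_parse_number(c, dialect, "fraction column") for c in fx]
            if any(b <= a for a, b in zip(fvol, fvol[1:])):
                raise FormatError("fraction volumes are not strictly increasing")
            fraction_events = [FractionEvent(v, lab) for v, lab in zip(fvol, flab)]
            icol += 2
            continue
        ys = _column_cells(rows, icol, 2)
        if not name and not ys:
            icol += 1
            continue
        if len(ys) > len(x):
            raise FormatError(f"curve {name!r} is longer than the volume column")
        for i, c in enumerate(ys):
            if not c:
                raise FormatError(
                    f"curve {name!r}: empty cell inside data at row {i + 3}"
                )
        y = [_parse_number(c, dialect, f"curve {name!r}") for c in ys]
        if len(y) < 2:
            meta.warnings.append(f"column {name!r} has fewer than 2 points; skipped")
            icol += 1
            continue
        curves.append(
            Curve(name=name or f"curve {icol}", x=x[: len(y)], y=y, x_unit=x_unit, y_unit=unit)
        )
        icol += 1

    if not curves:
        raise FormatError("template contains no curve columns")
    return Chromatogram(curves=curves, fraction_events=fraction_events, meta=meta)


def write_template(chrom: Chromatogram, target) -> None:
    """Write the generic shared-x template (UTF-8, tab-separated).

    All curves must share the volume grid of the longest curve as a prefix;
    otherwise the layout cannot represent the run and a ``ValueError`` is
    raised.
    """
    if not chrom.curves:
        raise ValueError("cannot write a chromatogram with zero curves")
    dialect = DialectDescriptor(column_pairing=False)
    longest = max(chrom.curves, key=len)
    for c in chrom.curves:
        if not np.array_equal(c.x, longest.x[: len(c)]):
            raise ValueError(
                f"curve {c.name!r} does not share the volume grid; the template "
                "layout requires a common x column"
            )
    header1 = ["Volume"] + [c.name for c in chrom.curves]
    header2 = [longest.x_unit] + [c.y_unit for c in chrom.curves]
    cols: list[list[str]] = [[_format_number(v, dialect) for v in longest.x]]
    for c in chrom.curves:
        cols.append([_format_number(v, dialect) for v in c.y])
    if chrom.fraction_events:
        header1 += ["Fraction start", "Fraction"]
        header2 += ["ml", "(Fractions)"]
        cols.append([_format_number(e.start_ml, dialect) for e in chrom.fraction_events])
        cols.append([e.label for e in chrom.fraction_events])
    nrows = max(len(c) for c in cols)
    lines = ["\t".join(header1), "\t".join(header2)]
    for i in range(nrows):
        lines.append("\t".join(col[i] if i < len(col) else "" for col in cols))
    _write_text("\n".join(lines) + "\n", target, "utf-8")


def blank_template(n_example_rows: int = 5) -> str:
    """A blank template users can fill with data from any instrument."""
    lines = [
        "Volume\tUV 280\tUV 260\tFraction start\tFraction",
        "ml\tmAU\tmAU\tml\t(Fractions)",
    ]
    for i in range(n_example_rows):
        frac = f"{float(i)!r}\t{i + 1}" if i < 2 else "\t"
        lines.append(f"{float(i)!r}\t0.0\t0.0\t{frac}")
    return "\n".join(lines) + "\n"
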