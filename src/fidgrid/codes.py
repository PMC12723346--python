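"""Coordinate-encoding fiducial symbols ("codes").

Each code embeds its own integer grid coordinate as machine-readable
geometry built from axis-aligned rectangles.  Four coding schemes are
supported:

``binary``
    A 7x7 cell lattice (cell side = minimum feature size ``f``).  Cell
    (0, 0) is the always-filled align mark; cells (1..6, 0) carry the x
    bits and cells (0, 1..6) the y bits, most-significant bit adjacent
    to the align mark.  Footprint: ``7f x 7f``.
``ternary``
    Same lattice; each cell encodes a trit by bar thickness: 0 = empty,
    1 = half-width bar, 2 = full square.
``decimal``
    Rectilinear seven-segment digits (stroke ``f``, glyph ``3f x 5f``),
    x-digit row above y-digit row, above a full-width align bar.
``planet``
    Postal-style tall/short bar code: five bars per digit (two tall of
    height ``5f``, three short of ``2f``), bar width ``f``, gap ``f``,
    delimited by two full-height frame bars that serve as align marks.

All geometry lives in a local frame in micrometres with the origin at
the align-mark outer corner; x grows right, y grows up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import CoordinateRangeError, SymbolError

__all__ = [
    "Scheme",
    "GridSpec",
    "GridCoordinate",
    "CodeGeometry",
    "encode",
    "logical_decode",
    "symbols_of",
    "footprint",
    "symbols_for_index",
    "index_for_symbols",
    "PLANET_TALL_POSITIONS",
    "SEVEN_SEGMENT",
]


class Scheme(str, Enum):
    BINARY = "binary"
    TERNARY = "ternary"
    DECIMAL = "decimal"
    PLANET = "planet"


_BASE = {Scheme.BINARY: 2, Scheme.TERNARY: 3, Scheme.DECIMAL: 10, Scheme.PLANET: 10}
_DEFAULT_SYMBOLS = {Scheme.BINARY: 6, Scheme.TERNARY: 6, Scheme.DECIMAL: 2, Scheme.PLANET: 2}

#: Positions (0 = leftmost of five bars) of the two tall bars per digit,
#: using the postal weight table 7-4-2-1-0 (weight sum 11 encodes 0).
PLANET_TALL_POSITIONS = {
    0: (0, 1),
    1: (3, 4),
    2: (2, 4),
    3: (2, 3),
    4: (1, 4),
    5: (1, 3),
    6: (1, 2),
    7: (0, 4),
    8: (0, 3),
    9: (0, 2),
}

#: Lit segments per decimal digit; a=top, b=top-right, c=bottom-right,
#: d=bottom, e=bottom-left, f=top-left, g=middle.
SEVEN_SEGMENT = {
    0: "abcdef",
    1: "bc",
    2: "abged",
    3: "abgcd",
    4: "fgbc",
    5: "afgcd",
    6: "afgedc",
    7: "abc",
    8: "abcdefg",
    9: "abcdfg",
}


@dataclass(frozen=True)
class GridSpec:
    """Design parameters governing every code geometry in a grid.

    Parameters
    ----------
    scheme:
        Coding scheme.
    feature_size:
        Minimum feature size ``f`` in micrometres — the side of a single
        bit square and the smallest fabricated dimension.
    spacing:
        Inter-marker pitch in micrometres; must exceed the code footprint
        so codes never overlap.
    symbols_per_axis:
        Bits (binary), trits (ternary) or digits (decimal/planet) per
        axis.  Defaults: 6 for binary/ternary, 2 for decimal/planet.
    fill_factor:
        Drawn square side as a fraction of ``f`` (lattice schemes only).
    """

    scheme: Scheme = Scheme.BINARY
    feature_size: float = 10.0
    spacing: float = 500.0
    symbols_per_axis: int | None = None
    fill_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if self.symbols_per_axis is None:
            object.__setattr__(self, "symbols_per_axis", _DEFAULT_SYMBOLS[self.scheme])
        if self.feature_size <= 0:
            raise ValueError("feature_size must be positive")
        if not (0 < self.fill_factor <= 1):
            raise ValueError("fill_factor must lie in (0, 1]")
        if self.symbols_per_axis < 1:
            raise ValueError("symbols_per_axis must be a positive integer")
        fp = footprint(self)
        if self.spacing <= max(fp):
            raise ValueError(
                f"spacing {self.spacing} um must exceed the code footprint {max(fp)} um"
            )

    @property
    def base(self) -> int:
        return _BASE[self.scheme]

    @property
    def addressable(self) -> int:
        """Addressable range per axis (``base ** symbols_per_axis``)."""
        return self.base ** self.symbols_per_axis

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "feature_size": self.feature_size,
            "spacing": self.spacing,
            "symbols_per_axis": self.symbols_per_axis,
            "fill_factor": self.fill_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass(frozen=True, order=True)
class GridCoordinate:
    """Integer grid address of one code site."""

    x_index: int
    y_index: int

    def __post_init__(self) -> None:
        if self.x_index < 0 or self.y_index < 0:
            raise CoordinateRangeError("grid indices must be non-negative")


@dataclass(frozen=True)
class CodeGeometry:
    """Realized geometry of one code symbol.

    ``rectangles`` are ``(x0, y0, x1, y1)`` in micrometres in the local
    frame (origin at the align-mark outer corner).  Rectangles are
    pairwise disjoint and lie inside ``footprint``.
    """

    rectangles: tuple[tuple[float, float, float, float], ...]
    footprint: tuple[float, float]


def _check_range(coord: GridCoordinate, spec: GridSpec) -> None:
    cap = spec.addressable
    for axis, idx in (("x", coord.x_index), ("y", coord.y_index)):
        if not (0 <= idx < cap):
            raise CoordinateRangeError(
                f"{axis}_index {idx} outside the {spec.scheme.value} scheme capacity "
                f"of {cap} addresses per axis"
            )


def symbols_for_index(index: int, spec: GridSpec) -> tuple[int, ...]:
    """Base expansion of one axis index, most-significant symbol first."""
    n, base = spec.symbols_per_axis, spec.base
    digits = []
    v = index
    for _ in range(n):
        digits.append(v % base)
        v //= base
    return tuple(reversed(digits))


def index_for_symbols(symbols: Sequence[int], spec: GridSpec) -> int:
    n, base = spec.symbols_per_axis, spec.base
    if len(symbols) != n:
        raise SymbolError(f"expected {n} symbols, got {len(symbols)}")
    v = 0
    for s in symbols:
        s = int(s)
        if not (0 <= s < base):
            raise SymbolError(f"symbol {s} outside alphabet 0..{base - 1}")
        v = v * base + s
    return v


def footprint(spec: GridSpec) -> tuple[float, float]:
    """Bounding-box size (width, height) of one code in micrometres.

    For the lattice schemes this is ``(n+1) f`` per side — seven times
    the minimum feature size at the default six symbols per axis (six
    bit cells plus the one-cell align mark).
    """
    f, n = spec.feature_size, spec.symbols_per_axis
    if spec.scheme in (Scheme.BINARY, Scheme.TERNARY):
        side = (n + 1) * f
        return (side, side)
    if spec.scheme is Scheme.DECIMAL:
        width = (4 * n - 1) * f  # n glyphs of 3f separated by f gaps
        height = 13.0 * f  # align bar + gap + y row (5f) + gap + x row (5f)
        return (width, height)
    # planet: two frame bars + 5 bars per digit per axis, gap f between bars
    nbars = 2 + 10 * n
    return ((2 * nbars - 1) * f, 5.0 * f)


def _cell_square(i: int, j: int, f: float, ff: float) -> tuple[float, float, float, float]:
    cx, cy = (i + 0.5) * f, (j + 0.5) * f
    h = 0.5 * ff * f
    return (cx - h, cy - h, cx + h, cy + h)


def _cell_bar(i: int, j: int, f: float, ff: float) -> tuple[float, float, float, float]:
    # half-width vertical bar for a ternary "1" trit
    cx, cy = (i + 0.5) * f, (j + 0.5) * f
    return (cx - 0.25 * ff * f, cy - 0.5 * ff * f, cx + 0.25 * ff * f, cy + 0.5 * ff * f)


def _encode_lattice(xs: Sequence[int], ys: Sequence[int], spec: GridSpec) -> list:
    f, ff = spec.feature_size, spec.fill_factor
    rects = [_cell_square(0, 0, f, ff)]  # align mark, always filled
    for k, s in enumerate(xs):  # MSB adjacent to align mark
        i = k + 1
        if s == 1 and spec.scheme is Scheme.TERNARY:
            rects.append(_cell_bar(i, 0, f, ff))
        elif s >= 1:
            rects.append(_cell_square(i, 0, f, ff))
    for k, s in enumerate(ys):
        j = k + 1
        if s == 1 and spec.scheme is Scheme.TERNARY:
            rects.append(_cell_bar(0, j, f, ff))
        elif s >= 1:
            rects.append(_cell_square(0, j, f, ff))
    return rects


# Disjoint rectangles for the seven segments of a 3f x 5f glyph with
# stroke f; (x0, y0, x1, y1) in units of f relative to the glyph origin.
_SEGMENT_RECTS = {
    "d": (0, 0, 3, 1),
    "g": (0, 2, 3, 3),
    "a": (0, 4, 3, 5),
    "e": (0, 1, 1, 2),
    "c": (2, 1, 3, 2),
    "f": (0, 3, 1, 4),
    "b": (2, 3, 3, 4),
}


def _glyph_rects(digit: int, x0: float, y0: float, f: float) -> list:
    rects = []
    for seg in SEVEN_SEGMENT[digit]:
        a, b, c, d = _SEGMENT_RECTS[seg]
        rects.append((x0 + a * f, y0 + b * f, x0 + c * f, y0 + d * f))
    return rects


def _encode_decimal(xs: Sequence[int], ys: Sequence[int], spec: GridSpec) -> list:
    f = spec.feature_size
    width = footprint(spec)[0]
    rects = [(0.0, 0.0, width, f)]  # full-width align bar, unique in the glyph set
    for row_y, digits in ((2 * f, ys), (8 * f, xs)):  # x row above y row
        for k, d in enumerate(digits):
            rects.extend(_glyph_rects(d, k * 4 * f, row_y, f))
    return rects


def _encode_planet(xs: Sequence[int], ys: Sequence[int], spec: GridSpec) -> list:
    f = spec.feature_size
    tall, short = 5.0 * f, 2.0 * f
    heights = [tall]  # leading frame bar
    for d in list(xs) + list(ys):
        pos = PLANET_TALL_POSITIONS[d]
        heights.extend(tall if p in pos else short for p in range(5))
    heights.append(tall)  # trailing frame bar
    rects = []
    for k, h in enumerate(heights):
        x0 = 2 * k * f  # bar width f, gap f
        rects.append((x0, 0.0, x0 + f, h))
    return rects


def encode(coord: GridCoordinate, spec: GridSpec) -> CodeGeometry:
    """Realize the code geometry for one grid coordinate.

    Raises
    ------
    CoordinateRangeError
        If either index is outside ``spec.addressable``.
    """
    _check_range(coord, spec)
    xs = symbols_for_index(coord.x_index, spec)
    ys = symbols_for_index(coord.y_index, spec)
    if spec.scheme in (Scheme.BINARY, Scheme.TERNARY):
        rects = _encode_lattice(xs, ys, spec)
    elif spec.scheme is Scheme.DECIMAL:
        rects = _encode_decimal(xs, ys, spec)
    else:
        rects = _encode_planet(xs, ys, spec)
    return CodeGeometry(rectangles=tuple(rects), footprint=footprint(spec))


def logical_decode(
    x_symbols: Sequence[int], y_symbols: Sequence[int], spec: GridSpec
) -> GridCoordinate:
    """Inverse of the symbol expansion: symbol vectors to coordinate."""
    return GridCoordinate(
        index_for_symbols(x_symbols, spec), index_for_symbols(y_symbols, spec)
    )


def _lattice_symbols(geom: CodeGeometry, spec: GridSpec) -> tuple[tuple, tuple]:
    f, n = spec.feature_size, spec.symbols_per_axis
    occupancy: dict[tuple[int, int], float] = {}
    for (x0, y0, x1, y1) in geom.rectangles:
        i = int(math.floor((x0 + x1) / 2 / f))
        j = int(math.floor((y0 + y1) / 2 / f))
        occupancy[(i, j)] = x1 - x0
    if (0, 0) not in occupancy:
        raise SymbolError("align mark missing from geometry")

    def trit(width: float | None) -> int:
        if width is None:
            return 0
        if spec.scheme is Scheme.TERNARY and width < 0.6 * spec.fill_factor * f:
            return 1
        return 1 if spec.scheme is Scheme.BINARY else 2

    xs = tuple(trit(occupancy.get((k + 1, 0))) for k in range(n))
    ys = tuple(trit(occupancy.get((0, k + 1))) for k in range(n))
    return xs, ys


def _decimal_symbols(geom: CodeGeometry, spec: GridSpec) -> tuple[tuple, tuple]:
    f, n = spec.feature_size, spec.symbols_per_axis
    inv_seg = {v: k for k, v in _SEGMENT_RECTS.items()}
    rows: dict[float, dict[int, set]] = {2 * f: {}, 8 * f: {}}
    for (x0, y0, x1, y1) in geom.rectangles:
        if y1 - y0 <= f * 1.01 and x1 - x0 > 3.5 * f:  # only the align bar is wider than a glyph
            continue  # align bar
        k = int(math.floor(x0 / (4 * f) + 1e-9))
        row_y = 2 * f if y0 < 7.5 * f else 8 * f
        gx, gy = x0 - k * 4 * f, y0 - row_y
        key = (round(gx / f), round(gy / f), round((x1 - x0) / f + gx / f),
               round((y1 - y0) / f + gy / f))
        rows[row_y].setdefault(k, set()).add(inv_seg[key])

    inv_digit = {frozenset(v): k for k, v in SEVEN_SEGMENT.items()}

    def digits(row: dict[int, set]) -> tuple:
        return tuple(inv_digit[frozenset(row.get(k, set()))] for k in range(n))

    return digits(rows[8 * f]), digits(rows[2 * f])


def _planet_symbols(geom: CodeGeometry, spec: GridSpec) -> tuple[tuple, tuple]:
    f, n = spec.feature_size, spec.symbols_per_axis
    inv = {v: k for k, v in PLANET_TALL_POSITIONS.items()}
    heights = {}
    for (x0, y0, x1, y1) in geom.rectangles:
        heights[round(x0 / (2 * f))] = y1 - y0
    nbars = 2 + 10 * n
    if heights.get(0) is None or heights.get(nbars - 1) is None:
        raise SymbolError("frame bars missing from geometry")
    digits = []
    for d in range(2 * n):
        bars = [heights[1 + 5 * d + p] for p in range(5)]
        tallpos = tuple(p for p, h in enumerate(bars) if h > 3.5 * f)
        if tallpos not in inv:
            raise SymbolError(f"invalid tall-bar pattern {tallpos}")
        digits.append(inv[tallpos])
    return tuple(digits[:n]), tuple(digits[n:])


def symbols_of(geom: CodeGeometry, spec: GridSpec) -> tuple[tuple, tuple]:
    """Read back (x_symbols, y_symbols) from a code geometry.

    Pure geometric introspection — the inverse of :func:`encode` at the
    symbol level, used for logical round-trip audits.
    """
    if spec.scheme in (Scheme.BINARY, Scheme.TERNARY):
        return _lattice_symbols(geom, spec)
    if spec.scheme is Scheme.DECIMAL:
        return _decimal_symbols(geom, spec)
    return _planet_symbols(geom, spec)
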