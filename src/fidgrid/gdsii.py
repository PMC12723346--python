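"""Minimal GDSII stream-format writer/reader.

Covers the record subset needed for planar mask layouts built from
axis-aligned rectangles: library header with explicit database/user
units, one structure per unique code, BOUNDARY elements, and SREF
placements from a single top cell.  Coordinates are integer database
units (1 nm by default), so a write -> read cycle is lossless at the
nanometre.

The 8-byte GDSII real is sign/7-bit excess-64 hexadecimal exponent/
56-bit mantissa; both directions of that codec live here.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from datetime import datetime

__all__ = ["GdsLibrary", "GdsStructure", "write_gds", "read_gds",
           "pack_real8", "unpack_real8"]

# record types
_HEADER = 0x00
_BGNLIB = 0x01
_LIBNAME = 0x02
_UNITS = 0x03
_ENDLIB = 0x04
_BGNSTR = 0x05
_STRNAME = 0x06
_ENDSTR = 0x07
_BOUNDARY = 0x08
_SREF = 0x0A
_LAYER = 0x0D
_DATATYPE = 0x0E
_XY = 0x10
_ENDEL = 0x11
_SNAME = 0x12


def pack_real8(value: float) -> bytes:
    """Encode a float as an 8-byte GDSII excess-64 base-16 real.

    Exact rational arithmetic keeps the 56-bit mantissa faithful to the
    input double (no intermediate float rounding).
    """
    from fractions import Fraction

    if value == 0:
        return b"\x00" * 8
    sign = 0x80 if value < 0 else 0
    v = Fraction(abs(value))
    exponent = 0
    while v >= 1:
        v /= 16
        exponent += 1
    while v < Fraction(1, 16):
        v *= 16
        exponent -= 1
    mantissa = round(v * (1 << 56))
    if mantissa >= 1 << 56:  # rounding overflow into the next power of 16
        mantissa >>= 4
        exponent += 1
    return bytes([sign | (exponent + 64)]) + mantissa.to_bytes(7, "big")


def unpack_real8(raw: bytes) -> float:
    if raw == b"\x00" * 8:
        return 0.0
    sign = -1.0 if raw[0] & 0x80 else 1.0
    exponent = (raw[0] & 0x7F) - 64
    mantissa = int.from_bytes(raw[1:8], "big") / float(1 << 56)
    return sign * mantissa * 16.0 ** exponent


def _record(rectype: int, datatype: int, payload: bytes = b"") -> bytes:
    return struct.pack(">HBB", 4 + len(payload), rectype, datatype) + payload


def _ascii(rectype: int, text: str) -> bytes:
    data = text.encode("ascii")
    if len(data) % 2:
        data += b"\x00"
    return _record(rectype, 0x06, data)


def _timestamps() -> bytes:
    t = datetime(2000, 1, 1)  # fixed stamp: byte-reproducible output
    rec = struct.pack(">6h", t.year, t.month, t.day, t.hour, t.minute, t.second)
    return rec + rec


@dataclass
class GdsStructure:
    name: str
    #: rectangles in database units: (x0, y0, x1, y1, layer, datatype)
    rectangles: list = field(default_factory=list)
    #: placements of other structures: (name, x_db, y_db)
    references: list = field(default_factory=list)


@dataclass
class GdsLibrary:
    name: str = "FIDGRID"
    db_unit_in_meters: float = 1e-9
    db_unit_in_user_units: float = 1e-3
    structures: dict = field(default_factory=dict)

    def add(self, structure: GdsStructure) -> "GdsLibrary":
        self.structures[structure.name] = structure
        return self

    def flatten(self, top: str) -> list:
        """All rectangles of ``top`` with references resolved, in db units."""
        out = []

        def visit(name: str, ox: int, oy: int) -> None:
            s = self.structures[name]
            out.extend((x0 + ox, y0 + oy, x1 + ox, y1 + oy, ly, dt)
                       for (x0, y0, x1, y1, ly, dt) in s.rectangles)
            for (child, rx, ry) in s.references:
                visit(child, ox + rx, oy + ry)

        visit(top, 0, 0)
        return out


def write_gds(library: GdsLibrary, path) -> None:
    chunks = [
        _record(_HEADER, 0x02, struct.pack(">h", 600)),
        _record(_BGNLIB, 0x02, _timestamps()),
        _ascii(_LIBNAME, library.name),
        _record(_UNITS, 0x05,
                pack_real8(library.db_unit_in_user_units)
                + pack_real8(library.db_unit_in_meters)),
    ]
    for s in library.structures.values():
        chunks.append(_record(_BGNSTR, 0x02, _timestamps()))
        chunks.append(_ascii(_STRNAME, s.name))
        for (x0, y0, x1, y1, layer, datatype) in s.rectangles:
            xy = struct.pack(">10i", x0, y0, x1, y0, x1, y1, x0, y1, x0, y0)
            chunks += [
                _record(_BOUNDARY, 0x00),
                _record(_LAYER, 0x02, struct.pack(">h", layer)),
                _record(_DATATYPE, 0x02, struct.pack(">h", datatype)),
                _record(_XY, 0x03, xy),
                _record(_ENDEL, 0x00),
            ]
        for (name, rx, ry) in s.references:
            chunks += [
                _record(_SREF, 0x00),
                _ascii(_SNAME, name),
                _record(_XY, 0x03, struct.pack(">2i", rx, ry)),
                _record(_ENDEL, 0x00),
            ]
        chunks.append(_record(_ENDSTR, 0x00))
    chunks.append(_record(_ENDLIB, 0x00))
    with open(path, "wb") as fh:
        fh.write(b"".join(chunks))


def read_gds(path) -> GdsLibrary:
    with open(path, "rb") as fh:
        raw = fh.read()
    lib = GdsLibrary()
    pos = 0
    current: GdsStructure | None = None
    element: str | None = None
    layer = datatype = 0
    sname = ""
    while pos < len(raw):
        (length,) = struct.unpack(">H", raw[pos:pos + 2])
        rectype = raw[pos + 2]
        payload = raw[pos + 4:pos + length]
        pos += length
        if rectype == _LIBNAME:
            lib.name = payload.rstrip(b"\x00").decode("ascii")
        elif rectype == _UNITS:
            lib.db_unit_in_user_units = unpack_real8(payload[:8])
            lib.db_unit_in_meters = unpack_real8(payload[8:16])
        elif rectype == _STRNAME:
            current = GdsStructure(payload.rstrip(b"\x00").decode("ascii"))
            lib.add(current)
        elif rectype == _BOUNDARY:
            element = "boundary"
        elif rectype == _SREF:
            element = "sref"
        elif rectype == _LAYER:
            (layer,) = struct.unpack(">h", payload)
        elif rectype == _DATATYPE:
            (datatype,) = struct.unpack(">h", payload)
        elif rectype == _SNAME:
            sname = payload.rstrip(b"\x00").decode("ascii")
        elif rectype == _XY and current is not None:
            coords = struct.unpack(f">{len(payload) // 4}i", payload)
            if element == "boundary":
                xs, ys = coords[0::2], coords[1::2]
                current.rectangles.append(
                    (min(xs), min(ys), max(xs), max(ys), layer, datatype))
            elif element == "sref":
                current.references.append((sname, coords[0], coords[1]))
        elif rectype == _ENDEL:
            element = None
        elif rectype == _ENDLIB:
            break
    return lib
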