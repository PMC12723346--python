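"""Grid layout: code placement, density arithmetic, and mask export.

The pitch between codes is sized by the *bottleneck* field of view —
the most constrained instrument in the workflow — so that any
axis-aligned FOV-sized window is guaranteed to contain at least one
fully visible code.  Layouts export to GDSII (1 nm database unit by
default), SVG previews, and JSON.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from . import gdsii
from .codes import GridCoordinate, GridSpec, encode, footprint
from .errors import CapacityError, InfeasibleSpacingError

__all__ = [
    "GridLayout",
    "select_spacing",
    "marker_density",
    "magnification_fold_range",
    "generate_grid",
    "write_gdsii",
    "read_gdsii_rectangles",
    "write_preview",
]

TOP_CELL_NAME = "MUGRID"


@dataclass(frozen=True)
class GridLayout:
    """Codes placed on a regular lattice inside a rectangular extent.

    Each placement anchors a code's align-mark corner at
    ``(x_index * spacing, y_index * spacing)``; physical y grows "up".
    """

    spec: GridSpec
    extent: tuple[float, float]
    placements: tuple[tuple[GridCoordinate, tuple[float, float]], ...]

    def __len__(self) -> int:
        return len(self.placements)

    def to_json(self, path=None) -> str:
        doc = {
            "spec": self.spec.to_dict(),
            "extent": list(self.extent),
            "placements": [
                [c.x_index, c.y_index, ax, ay] for c, (ax, ay) in self.placements
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GridLayout":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            spec=GridSpec.from_dict(doc["spec"]),
            extent=tuple(doc["extent"]),
            placements=tuple(
                (GridCoordinate(xi, yi), (ax, ay))
                for xi, yi, ax, ay in doc["placements"]
            ),
        )


def select_spacing(fov: float, spec: GridSpec, quantum: float = 100.0) -> float:
    """Largest quantized pitch guaranteeing >= 1 full code per FOV window.

    Returns the largest multiple ``S`` of ``quantum`` satisfying
    ``S + max(footprint) <= fov``: wherever an ``fov x fov`` window
    lands on the grid, at least one code lies fully inside it along
    each axis.

    Raises
    ------
    InfeasibleSpacingError
        If no such multiple exceeds the code footprint.
    """
    fp = max(footprint(spec))
    if fov <= fp + quantum:
        raise InfeasibleSpacingError(
            f"field of view {fov} um cannot hold an {fp} um code plus a "
            f"positive pitch on a {quantum} um quantum"
        )
    s = math.floor((fov - fp) / quantum) * quantum
    if s <= fp:
        raise InfeasibleSpacingError(
            f"feasible pitch {s} um does not exceed the code footprint {fp} um"
        )
    return s


def marker_density(spacing: float) -> tuple[float, float]:
    """Markers per mm^2 and per cm^2 for a square grid at ``spacing`` um."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    per_mm2 = (1000.0 / spacing) ** 2
    return per_mm2, per_mm2 * 100.0


def magnification_fold_range(high_magnification: float, low_magnification: float) -> float:
    """Fold range between the highest and lowest usable magnification.

    E.g. a structure readable from a 5X optical objective up to 1500X
    SEM spans a 300-fold range.
    """
    if low_magnification <= 0 or high_magnification <= 0:
        raise ValueError("magnifications must be positive")
    return high_magnification / low_magnification


def generate_grid(spec: GridSpec, extent: tuple[float, float]) -> GridLayout:
    """Populate every lattice site whose code fits inside ``extent``.

    Site (i, j) anchors at ``(i * spacing, j * spacing)`` and is kept
    when its full footprint lies inside the extent.  Coordinates are
    unique by construction.

    Raises
    ------
    CapacityError
        If the extent needs more sites per axis than the scheme can
        address.
    """
    w, h = extent
    fw, fh = footprint(spec)
    s = spec.spacing
    nx = max(0, math.floor((w - fw) / s) + 1) if w >= fw else 0
    ny = max(0, math.floor((h - fh) / s) + 1) if h >= fh else 0
    if nx > spec.addressable or ny > spec.addressable:
        raise CapacityError(
            f"extent needs {max(nx, ny)} sites per axis but the "
            f"{spec.scheme.value} scheme addresses only {spec.addressable}; "
            f"increase symbols_per_axis"
        )
    placements = tuple(
        (GridCoordinate(i, j), (i * s, j * s))
        for j in range(ny)
        for i in range(nx)
    )
    return GridLayout(spec=spec, extent=(float(w), float(h)), placements=placements)


def _db(value_um: float, db_per_um: float) -> int:
    return int(round(value_um * db_per_um))


def write_gdsii(
    layout: GridLayout,
    path,
    layer: int = 1,
    datatype: int = 0,
    db_unit_nm: float = 1.0,
) -> None:
    """Write the layout as a GDSII stream file.

    Database unit is 1 nm (user unit 1 um) by default; every code
    becomes one structure referenced from the top cell ``MUGRID``, so
    re-reading the file reproduces each rectangle to the nanometre.
    """
    db_per_um = 1000.0 / db_unit_nm
    lib = gdsii.GdsLibrary(
        name="FIDGRID",
        db_unit_in_meters=db_unit_nm * 1e-9,
        db_unit_in_user_units=db_unit_nm * 1e-3,
    )
    top = gdsii.GdsStructure(TOP_CELL_NAME)
    for coord, (ax, ay) in layout.placements:
        name = f"CODE_X{coord.x_index}_Y{coord.y_index}"
        geom = encode(coord, layout.spec)
        struct_ = gdsii.GdsStructure(
            name,
            rectangles=[
                (_db(x0, db_per_um), _db(y0, db_per_um),
                 _db(x1, db_per_um), _db(y1, db_per_um), layer, datatype)
                for (x0, y0, x1, y1) in geom.rectangles
            ],
        )
        lib.add(struct_)
        top.references.append((name, _db(ax, db_per_um), _db(ay, db_per_um)))
    lib.add(top)
    gdsii.write_gds(lib, path)


def read_gdsii_rectangles(path, top: str = TOP_CELL_NAME):
    """Parse a layout GDSII back to flattened rectangles in micrometres.

    Returns ``(library, rectangles)`` where rectangles are
    ``(x0, y0, x1, y1, layer, datatype)`` in um.
    """
    lib = gdsii.read_gds(path)
    um_per_db = lib.db_unit_in_meters * 1e6
    rects = [
        (x0 * um_per_db, y0 * um_per_db, x1 * um_per_db, y1 * um_per_db, ly, dt)
        for (x0, y0, x1, y1, ly, dt) in lib.flatten(top)
    ]
    return lib, rects


def write_preview(layout: GridLayout, path) -> None:
    """Vector (SVG) preview of the layout, y-up physical frame."""
    w, h = layout.extent
    root = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=f"{w}", height=f"{h}",
        viewBox=f"0 0 {w} {h}",
    )
    # flip: SVG y grows down, physical y grows up
    world = ET.SubElement(root, "g", transform=f"translate(0,{h}) scale(1,-1)")
    for coord, (ax, ay) in layout.placements:
        group = ET.SubElement(
            world, "g",
            attrib={"class": "code",
                    "data-x": str(coord.x_index), "data-y": str(coord.y_index)},
        )
        for (x0, y0, x1, y1) in encode(coord, layout.spec).rectangles:
            ET.SubElement(
                group, "rect",
                x=f"{ax + x0}", y=f"{ay + y0}",
                width=f"{x1 - x0}", height=f"{y1 - y0}",
            )
    ET.ElementTree(root).write(path)
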