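"""Synthetic microscope imaging of code grids.

A parametric camera model renders a :class:`~fidgrid.layout.GridLayout`
into a grayscale frame: each rectangle is deformed (substrate model),
mapped physical -> image by a similarity (pixel size, in-plane rotation,
translation of the image centre), rasterized with area-weighted
anti-aliasing, convolved with a Gaussian PSF proxy, polarity-encoded
(dark features on bright background emulates brightfield; bright on
dark emulates darkfield / secondary-electron SEM), and corrupted with
additive Gaussian noise.  Rendering is deterministic for a fixed seed.

Conventions: physical frame is micrometres, y up.  Image row index
grows "down" (row axis = -y), so a point at physical (x, y) relative to
the camera centre lands at ``col = cc + x'/p``, ``row = rc - y'/p``
after rotating by the camera angle.  Pixel centres sit at integer
indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .codes import encode, footprint
from .layout import GridLayout

__all__ = ["CameraModel", "DeformationField", "render", "ground_truth",
           "save_image", "load_image"]


@dataclass(frozen=True)
class DeformationField:
    """Substrate deformation applied in the physical frame.

    Models: ``none``; ``uniform_scale`` (single factor ``sx``);
    ``anisotropic_scale`` (``sx``, ``sy``); ``piecewise_affine`` — a
    table of rectangular regions that tile the extent, each with its own
    2x3 affine matrix, emulating local swelling/shrinkage/warping.
    """

    model: Literal["none", "uniform_scale", "anisotropic_scale",
                   "piecewise_affine"] = "none"
    sx: float = 1.0
    sy: float = 1.0
    #: list of (x0, y0, x1, y1, 2x3 matrix) for piecewise_affine
    regions: tuple = ()

    def __post_init__(self) -> None:
        if self.model == "uniform_scale":
            object.__setattr__(self, "sy", self.sx)
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")
        if self.model == "piecewise_affine" and not self.regions:
            raise ValueError("piecewise_affine needs a region table")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        if self.model == "none":
            return pts
        if self.model in ("uniform_scale", "anisotropic_scale"):
            return pts * np.array([self.sx, self.sy])
        out = np.empty_like(pts)
        for k, (x, y) in enumerate(pts):
            for (x0, y0, x1, y1, m) in self.regions:
                if x0 <= x <= x1 and y0 <= y <= y1:
                    m = np.asarray(m, float)
                    out[k] = m[:, :2] @ (x, y) + m[:, 2]
                    break
            else:
                raise ValueError(f"point ({x}, {y}) outside the deformation tiling")
        return out


@dataclass(frozen=True)
class CameraModel:
    """Imaging geometry and photometry of one synthetic acquisition."""

    pixel_size: float  # um per pixel
    image_size: tuple[int, int] = (512, 512)  # (rows, cols)
    rotation: float = 0.0  # degrees, stage-to-image, about the optical axis
    translation: tuple[float, float] = (0.0, 0.0)  # physical um of image centre
    polarity: Literal["dark_features", "bright_features"] = "bright_features"
    blur_sigma: float = 0.0  # um, Gaussian PSF proxy
    noise_sigma: float = 0.0  # fraction of dynamic range
    background: float = 0.5  # intensity fraction
    contrast: float = 0.45  # |feature - background| in intensity fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be non-negative")

    def phys_to_pixel(self, points: np.ndarray) -> np.ndarray:
        """Map physical um points (N, 2) to (row, col) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points, float)) - np.asarray(self.translation)
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        ux = c * pts[:, 0] - s * pts[:, 1]
        uy = s * pts[:, 0] + c * pts[:, 1]
        rows, cols = self.image_size
        rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
        return np.column_stack([rc - uy / self.pixel_size,
                                cc + ux / self.pixel_size])


def _rasterize_quad(buf: np.ndarray, quad: np.ndarray, supersample: int = 4) -> None:
    """Accumulate the pixel coverage of a convex quad given in (row, col)."""
    rows, cols = buf.shape
    rmin = max(0, int(math.floor(quad[:, 0].min() - 0.5)))
    rmax = min(rows - 1, int(math.ceil(quad[:, 0].max() + 0.5)))
    cmin = max(0, int(math.floor(quad[:, 1].min() - 0.5)))
    cmax = min(cols - 1, int(math.ceil(quad[:, 1].max() + 0.5)))
    if rmin > rmax or cmin > cmax:
        return
    ss = supersample
    off = (np.arange(ss) + 0.5) / ss - 0.5
    rr = (np.arange(rmin, rmax + 1)[:, None] + off[None, :]).ravel()
    cc = (np.arange(cmin, cmax + 1)[:, None] + off[None, :]).ravel()
    R, C = np.meshgrid(rr, cc, indexing="ij")
    # signed area orientation of the quad
    x, y = quad[:, 1], quad[:, 0]
    orient = math.copysign(1.0, np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    inside = np.ones(R.shape, bool)
    for k in range(4):
        p, q = quad[k], quad[(k + 1) % 4]
        cross = (q[1] - p[1]) * (R - p[0]) - (q[0] - p[0]) * (C - p[1])
        inside &= orient * cross >= 0
    nr, nc = rmax - rmin + 1, cmax - cmin + 1
    cov = inside.reshape(nr, ss, nc, ss).mean(axis=(1, 3))
    buf[rmin:rmax + 1, cmin:cmax + 1] += cov


def render(
    layout: GridLayout,
    camera: CameraModel,
    deform: DeformationField | None = None,
) -> np.ndarray:
    """Render the layout to a float image in [0, 1] (before noise clip).

    Feature pixels sit at ``background + contrast`` (bright_features) or
    ``background - contrast`` (dark_features); flipping polarity mirrors
    the image about the background level.
    """
    deform = deform or DeformationField()
    coverage = np.zeros(camera.image_size, float)
    fw, fh = footprint(layout.spec)
    rows, cols = camera.image_size
    half_diag_px = math.hypot(fw, fh) / camera.pixel_size
    centre = np.asarray(camera.translation)
    view_radius = math.hypot(rows, cols) / 2.0 + half_diag_px + 2
    for coord, (ax, ay) in layout.placements:
        # cheap cull: skip codes far outside the frame
        anchor_px = camera.phys_to_pixel(deform.apply(np.array([[ax, ay]])))[0]
        if (abs(anchor_px[0] - (rows - 1) / 2) > view_radius
                or abs(anchor_px[1] - (cols - 1) / 2) > view_radius):
            continue
        geom = encode(coord, layout.spec)
        for (x0, y0, x1, y1) in geom.rectangles:
            corners = np.array([[ax + x0, ay + y0], [ax + x1, ay + y0],
                                [ax + x1, ay + y1], [ax + x0, ay + y1]])
            quad = camera.phys_to_pixel(deform.apply(corners))
            _rasterize_quad(coverage, quad)
    np.clip(coverage, 0.0, 1.0, out=coverage)
    sign = 1.0 if camera.polarity == "bright_features" else -1.0
    img = camera.background + sign * camera.contrast * coverage
    if camera.blur_sigma > 0:
        img = gaussian_filter(img, camera.blur_sigma / camera.pixel_size)
    if camera.noise_sigma > 0:
        rng = np.random.default_rng(camera.seed)
        img = img + rng.normal(0.0, camera.noise_sigma, img.shape)
    return img


def ground_truth(
    layout: GridLayout,
    camera: CameraModel,
    deform: DeformationField | None = None,
) -> pd.DataFrame:
    """True pixel positions of every fully visible code.

    Columns: ``x_index, y_index, px_row, px_col, orientation_deg`` —
    the align-mark corner position and the in-image angle of the grid
    +x axis (math convention on (col, -row)).  Codes whose footprint is
    not entirely inside the frame are omitted.
    """
    deform = deform or DeformationField()
    rows, cols = camera.image_size
    fw, fh = footprint(layout.spec)
    records = []
    for coord, (ax, ay) in layout.placements:
        corners = np.array([[ax, ay], [ax + fw, ay], [ax + fw, ay + fh], [ax, ay + fh]])
        px = camera.phys_to_pixel(deform.apply(corners))
        if (px[:, 0].min() < 0 or px[:, 0].max() > rows - 1
                or px[:, 1].min() < 0 or px[:, 1].max() > cols - 1):
            continue
        probe = camera.phys_to_pixel(deform.apply(
            np.array([[ax, ay], [ax + 1.0, ay]])))
        d = probe[1] - probe[0]
        orientation = math.degrees(math.atan2(-d[0], d[1]))
        records.append({
            "x_index": coord.x_index, "y_index": coord.y_index,
            "px_row": px[0, 0], "px_col": px[0, 1],
            "orientation_deg": orientation,
        })
    return pd.DataFrame.from_records(
        records, columns=["x_index", "y_index", "px_row", "px_col", "orientation_deg"]
    )


def save_image(img: np.ndarray, path) -> None:
    """Write a float image as 8-bit PNG or 16-bit TIFF by extension."""
    clipped = np.clip(img, 0.0, 1.0)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, (clipped * 65535).round().astype(np.uint16))
    else:
        from PIL import Image

        Image.fromarray((clipped * 255).round().astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale image as float in [0, 1]."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return arr.astype(float) / scale
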