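"""Fiducial-driven co-registration of multimodal image pairs.

Detections from two modalities (e.g. transmitted-light confocal and
SEM) are matched by their decoded grid coordinate — no intensity-based
matching is needed because every fiducial is globally unique.  A
similarity (default; rotation + scale + translation) or affine
transform mapping moving -> fixed pixels is fitted in least squares,
and the moving image is resampled into the fixed frame for an alpha
composite, as in classic overlay figures (top image at 50%
transparency).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from ._transform import decompose_affine, fit_affine, umeyama
from .codes import GridCoordinate
from .decode import DetectedCode
from .errors import InsufficientCorrespondenceError

logger = logging.getLogger("fidgrid.register")

__all__ = [
    "CorrespondenceSet",
    "ImageTransform",
    "match_by_code",
    "estimate_transform",
    "warp_moving",
    "warp_and_overlay",
    "registration_report",
]


@dataclass(frozen=True)
class CorrespondenceSet:
    """Matched fiducial pixel positions across two images.

    ``pairs`` holds ``(coordinate, (row, col) fixed, (row, col) moving)``;
    coordinates are unique within the set.
    """

    pairs: tuple
    fixed_label: str = "fixed"
    moving_label: str = "moving"
    unmatched_fixed: tuple = ()
    unmatched_moving: tuple = ()


@dataclass(frozen=True)
class ImageTransform:
    """2x3 pixel-frame transform, moving -> fixed.

    Row-major matrix in (x=col, y=row) convention:
    ``[col_f, row_f]^T = matrix[:, :2] @ [col_m, row_m]^T + matrix[:, 2]``.
    """

    model: Literal["similarity", "affine"]
    matrix: np.ndarray
    rms_residual: float

    def apply(self, positions) -> np.ndarray:
        """Map (N, 2) moving (row, col) positions into the fixed frame."""
        pts = np.atleast_2d(np.asarray(positions, float))
        xy = pts[:, ::-1]  # to (col, row)
        out = xy @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out[:, ::-1]

    def inverse(self) -> "ImageTransform":
        L = self.matrix[:, :2]
        Li = np.linalg.inv(L)
        t = -Li @ self.matrix[:, 2]
        return ImageTransform(self.model, np.column_stack([Li, t]),
                              self.rms_residual)

    def to_json(self, path=None) -> str:
        sx, sy, theta, shear, refl = decompose_affine(self.matrix)
        doc = {
            "model": self.model,
            "matrix": [list(map(float, row)) for row in self.matrix],
            "theta_deg": math.degrees(theta),
            "scale_x": sx, "scale_y": sy, "shear": shear,
            "reflection": bool(refl),
            "rms_residual": self.rms_residual,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ImageTransform":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(doc["model"], np.asarray(doc["matrix"], float),
                   doc["rms_residual"])


def match_by_code(
    detections_fixed: Sequence[DetectedCode],
    detections_moving: Sequence[DetectedCode],
    fixed_label: str = "fixed",
    moving_label: str = "moving",
) -> CorrespondenceSet:
    """Pair detections across modalities by identical grid coordinate.

    Duplicate coordinates within one set keep the higher-confidence
    detection (logged).  Raises
    :class:`~fidgrid.errors.InsufficientCorrespondenceError` when fewer
    than two coordinates are shared.
    """

    def dedupe(dets):
        best = {}
        for d in dets:
            key = (d.coordinate.x_index, d.coordinate.y_index)
            if key in best and best[key].confidence >= d.confidence:
                logger.info("duplicate coordinate %s: keeping the higher-"
                            "confidence detection", key)
                continue
            if key in best:
                logger.info("duplicate coordinate %s: keeping the higher-"
                            "confidence detection", key)
            best[key] = d
        return best

    fixed = dedupe(detections_fixed)
    moving = dedupe(detections_moving)
    shared = sorted(set(fixed) & set(moving))
    if len(shared) < 2:
        raise InsufficientCorrespondenceError(
            f"only {len(shared)} shared coordinate(s) between the two "
            f"detection sets; at least 2 are required"
        )
    pairs = tuple(
        (GridCoordinate(*key), fixed[key].position, moving[key].position)
        for key in shared
    )
    return CorrespondenceSet(
        pairs=pairs, fixed_label=fixed_label, moving_label=moving_label,
        unmatched_fixed=tuple(sorted(set(fixed) - set(moving))),
        unmatched_moving=tuple(sorted(set(moving) - set(fixed))),
    )


def estimate_transform(
    corr: CorrespondenceSet,
    model: Literal["similarity", "affine"] = "similarity",
) -> ImageTransform:
    """Least-squares fit of the moving -> fixed pixel transform.

    Exact (zero residual) at the minimal configuration (2 pairs for
    similarity, 3 for affine); otherwise the RMS residual is reported.
    """
    fixed = np.array([p[1] for p in corr.pairs], float)[:, ::-1]  # (col,row)
    moving = np.array([p[2] for p in corr.pairs], float)[:, ::-1]
    if model == "similarity":
        M, *_ = umeyama(moving, fixed, allow_reflection=True)
    elif model == "affine":
        M = fit_affine(moving, fixed)
    else:
        raise ValueError(f"unknown model {model!r}")
    pred = moving @ M[:, :2].T + M[:, 2]
    rms = float(np.sqrt(np.mean(np.sum((pred - fixed) ** 2, axis=1))))
    return ImageTransform(model=model, matrix=M, rms_residual=rms)


def warp_moving(
    moving: np.ndarray,
    transform: ImageTransform,
    output_shape=None,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample the moving image into the fixed frame (bilinear default).

    ``order=0`` gives nearest-neighbour for label images.
    """
    tf = AffineTransform(matrix=np.vstack([transform.matrix, [0, 0, 1]]))
    return warp(np.asarray(moving, float), tf.inverse,
                output_shape=output_shape, order=order, cval=cval,
                preserve_range=True)


def warp_and_overlay(
    fixed: np.ndarray,
    moving: np.ndarray,
    transform: ImageTransform,
    alpha: float = 0.5,
    tint: tuple | None = None,
    order: int = 1,
) -> np.ndarray:
    """Alpha composite of the warped moving image over the fixed one.

    ``composite = (1 - alpha) * fixed + alpha * warped``; with ``tint``
    (an RGB triple for the warped channel) the result is an RGB image
    with the fixed image as the gray base — the fluorescence-on-SEM
    style of overlay.
    """
    fixed = np.asarray(fixed, float)
    warped = warp_moving(moving, transform, output_shape=fixed.shape, order=order)
    if tint is None:
        return (1.0 - alpha) * fixed + alpha * warped
    tint = np.asarray(tint, float)
    base = np.repeat(fixed[..., None], 3, axis=2)
    return (1.0 - alpha) * base + alpha * warped[..., None] * tint[None, None, :]


def registration_report(
    corr: CorrespondenceSet,
    transform: ImageTransform,
    pixel_size: float | None = None,
) -> dict:
    """Per-pair residuals (px, and um when a pixel size is given)."""
    fixed = np.array([p[1] for p in corr.pairs], float)
    mapped = transform.apply([p[2] for p in corr.pairs])
    resid = np.linalg.norm(mapped - fixed, axis=1)
    table = pd.DataFrame({
        "x_index": [p[0].x_index for p in corr.pairs],
        "y_index": [p[0].y_index for p in corr.pairs],
        "residual_px": resid,
    })
    if pixel_size is not None:
        table["residual_um"] = resid * pixel_size
    return {
        "residuals": table,
        "rms_px": float(np.sqrt(np.mean(resid ** 2))),
        "max_px": float(resid.max()) if len(resid) else 0.0,
        "n_pairs": len(corr.pairs),
    }
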