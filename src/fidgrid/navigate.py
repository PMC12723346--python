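"""Instrument navigation: grid <-> stage coordinate calibration.

Re-implements the locator workflow: the user pinpoints two arbitrary
codes and enters their instrument (stage) coordinates; the calibration
solves the similarity transform between the grid's physical frame
(coordinate x pitch, micrometres) and the stage frame, including the
scale factor — the metric of substrate deformation (swelling or
shrinkage between fabrication and imaging).  With three or more
anchors an affine model resolves anisotropic deformation (the two
singular values of the linear part are per-axis scale factors); four
or more support a piecewise-affine model for local, non-uniform
compensation.

Stage units are whatever the session declares (um or mm) and are never
silently converted; the scale factor is stage-units per grid-um.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._transform import (
    decompose_affine,
    fit_affine,
    similarity_from_two_points,
    umeyama,
)
from .codes import GridCoordinate
from .errors import DegenerateGeometryError, SingularTransformError

__all__ = [
    "Anchor",
    "StageMapping",
    "calibrate",
    "grid_to_stage",
    "stage_to_grid",
    "deformation_report",
    "infer_reflection",
    "anchors_from_csv",
    "anchors_to_csv",
]


@dataclass(frozen=True)
class Anchor:
    """A code with known stage coordinates."""

    coordinate: GridCoordinate
    stage: tuple[float, float]


@dataclass
class StageMapping:
    """Fitted grid-physical -> stage transform."""

    model: Literal["similarity", "affine", "piecewise_affine"]
    matrix: np.ndarray  # 2x3, stage = matrix[:, :2] @ grid_um + matrix[:, 2]
    theta_deg: float
    scale: float  # isotropic scale factor (geometric mean for affine)
    sx: float
    sy: float
    reflection: bool
    rms_residual: float
    stage_units: str = "um"
    _piecewise: object | None = None
    _anchors_um: np.ndarray | None = None
    _anchors_stage: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        doc = {
            "model": self.model,
            "theta_deg": self.theta_deg,
            "scale": self.scale,
            "sx": self.sx,
            "sy": self.sy,
            "tx": float(self.matrix[0, 2]),
            "ty": float(self.matrix[1, 2]),
            "matrix": [list(map(float, row)) for row in self.matrix],
            "reflection": self.reflection,
            "rms_residual": self.rms_residual,
            "stage_units": self.stage_units,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _grid_um(anchors: Sequence[Anchor], spacing: float) -> np.ndarray:
    return np.array([(a.coordinate.x_index * spacing,
                      a.coordinate.y_index * spacing) for a in anchors], float)


def calibrate(
    anchors: Sequence[Anchor],
    spacing: float,
    model: Literal["similarity", "affine", "piecewise_affine"] = "similarity",
    reflection: bool = False,
    stage_units: str = "um",
) -> StageMapping:
    """Fit the grid -> stage transform from anchor codes.

    Two anchors determine a similarity exactly (zero residual by
    construction); more anchors are fitted in least squares and the RMS
    residual is reported.  Two anchors cannot distinguish a proper
    rotation from a mirrored view, so ``reflection`` must be supplied
    (see :func:`infer_reflection` to derive it from detections).

    Raises
    ------
    DegenerateGeometryError
        Coincident anchors (similarity) or collinear anchors (affine).
    """
    anchors = list(anchors)
    coords = {(a.coordinate.x_index, a.coordinate.y_index) for a in anchors}
    if len(coords) != len(anchors):
        raise DegenerateGeometryError("anchors must have distinct coordinates")
    src = _grid_um(anchors, spacing)
    dst = np.array([a.stage for a in anchors], float)

    if model == "similarity":
        if len(anchors) < 2:
            raise DegenerateGeometryError("similarity needs at least two anchors")
        if len(anchors) == 2:
            M = similarity_from_two_points(src, dst, reflection=reflection)
            scale = math.sqrt(abs(np.linalg.det(M[:, :2])))
            lin = M[:, :2] / scale
            if reflection:
                lin = lin @ np.array([[1.0, 0.0], [0.0, -1.0]])
            theta = math.atan2(lin[1, 0], lin[0, 0])
            rms = 0.0
        else:
            M, scale, theta, reflection = umeyama(
                src, dst, force_reflection=reflection)
            rms = _rms(M, src, dst)
        return StageMapping(
            model=model, matrix=M, theta_deg=math.degrees(theta),
            scale=float(scale), sx=float(scale), sy=float(scale),
            reflection=reflection, rms_residual=rms, stage_units=stage_units,
            _anchors_um=src, _anchors_stage=dst,
        )

    if model == "affine":
        M = fit_affine(src, dst)
        sx, sy, theta, _, refl = decompose_affine(M)
        return StageMapping(
            model=model, matrix=M, theta_deg=math.degrees(theta),
            scale=math.sqrt(sx * sy), sx=sx, sy=sy, reflection=refl,
            rms_residual=_rms(M, src, dst), stage_units=stage_units,
            _anchors_um=src, _anchors_stage=dst,
        )

    if model == "piecewise_affine":
        if len(anchors) < 4:
            raise DegenerateGeometryError("piecewise_affine needs >= 4 anchors")
        from skimage.transform import PiecewiseAffineTransform

        if hasattr(PiecewiseAffineTransform, "from_estimate"):
            tf = PiecewiseAffineTransform.from_estimate(src, dst)
            if not tf:
                raise DegenerateGeometryError("piecewise-affine estimation failed")
        else:  # scikit-image < 0.26
            tf = PiecewiseAffineTransform()
            if not tf.estimate(src, dst):
                raise DegenerateGeometryError("piecewise-affine estimation failed")
        M = fit_affine(src, dst)  # global summary of the local patches
        sx, sy, theta, _, refl = decompose_affine(M)
        return StageMapping(
            model=model, matrix=M, theta_deg=math.degrees(theta),
            scale=math.sqrt(sx * sy), sx=sx, sy=sy, reflection=refl,
            rms_residual=0.0,  # interpolates every anchor exactly
            stage_units=stage_units, _piecewise=tf,
            _anchors_um=src, _anchors_stage=dst,
        )

    raise ValueError(f"unknown model {model!r}")


def _rms(M, src, dst) -> float:
    pred = src @ M[:, :2].T + M[:, 2]
    return float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))


def grid_to_stage(
    mapping: StageMapping, coord: GridCoordinate, spacing: float
) -> tuple[float, float]:
    """Predict the stage position of a target code."""
    p = np.array([coord.x_index * spacing, coord.y_index * spacing], float)
    if mapping.model == "piecewise_affine" and mapping._piecewise is not None:
        inside = mapping._piecewise(p[None, :])[0]
        if np.all(np.isfinite(inside)):
            return (float(inside[0]), float(inside[1]))
        # outside the anchor hull: fall back to the global affine summary
    q = mapping.matrix[:, :2] @ p + mapping.matrix[:, 2]
    return (float(q[0]), float(q[1]))


def stage_to_grid(
    mapping: StageMapping, position: tuple[float, float], spacing: float
) -> tuple[GridCoordinate, float]:
    """Nearest grid coordinate for a stage position, plus the residual.

    The residual is the stage-frame distance between ``position`` and
    the predicted position of the rounded coordinate.  Midpoints round
    half toward the lower index.

    Raises
    ------
    SingularTransformError
        If the linear part cannot be inverted.
    """
    L = mapping.matrix[:, :2]
    if abs(np.linalg.det(L)) < 1e-12:
        raise SingularTransformError("mapping has a singular linear part")
    p = np.asarray(position, float)
    if mapping.model == "piecewise_affine" and mapping._piecewise is not None:
        q = mapping._piecewise.inverse(p[None, :])[0]
        if not np.all(np.isfinite(q)):
            q = np.linalg.solve(L, p - mapping.matrix[:, 2])
    else:
        q = np.linalg.solve(L, p - mapping.matrix[:, 2])
    idx = np.ceil(q / spacing - 0.5)  # half rounds toward the lower index
    idx = np.maximum(idx, 0).astype(int)
    coord = GridCoordinate(int(idx[0]), int(idx[1]))
    pred = np.asarray(grid_to_stage(mapping, coord, spacing))
    return coord, float(np.linalg.norm(pred - p))


def deformation_report(mapping: StageMapping) -> dict:
    """Decompose substrate deformation from an affine (or richer) fit.

    Returns the anisotropic scale factors (singular values of the
    linear part), rotation, shear, and a per-anchor residual table for
    outlier spotting.
    """
    if mapping.model == "similarity" and mapping._anchors_um is not None \
            and len(mapping._anchors_um) < 3:
        raise ValueError("deformation decomposition needs an affine-capable fit")
    sx, sy, theta, shear, refl = decompose_affine(mapping.matrix)
    table = None
    if mapping._anchors_um is not None:
        pred = mapping._anchors_um @ mapping.matrix[:, :2].T + mapping.matrix[:, 2]
        resid = np.linalg.norm(pred - mapping._anchors_stage, axis=1)
        table = pd.DataFrame({
            "grid_x_um": mapping._anchors_um[:, 0],
            "grid_y_um": mapping._anchors_um[:, 1],
            "stage_x": mapping._anchors_stage[:, 0],
            "stage_y": mapping._anchors_stage[:, 1],
            "residual": resid,
        })
    return {
        "sx": sx, "sy": sy, "theta_deg": math.degrees(theta),
        "shear": shear, "reflection": refl, "residuals": table,
    }


def infer_reflection(detections) -> bool:
    """Majority vote of the mirrored flag over a set of detections.

    The chiral L layout lets the decoder tell a mirrored view (e.g.
    imaging through the substrate) from a proper rotation, which two
    anchors alone cannot.
    """
    votes = [bool(getattr(d, "mirrored", False)) for d in detections]
    if not votes:
        raise ValueError("no detections to vote on")
    return sum(votes) * 2 > len(votes)


def anchors_from_csv(path) -> list[Anchor]:
    """Read an anchor table (columns x_index, y_index, stage_x, stage_y)."""
    frame = pd.read_csv(path)
    return [
        Anchor(GridCoordinate(int(r.x_index), int(r.y_index)),
               (float(r.stage_x), float(r.stage_y)))
        for r in frame.itertuples()
    ]


def anchors_to_csv(anchors: Sequence[Anchor], path) -> None:
    pd.DataFrame(
        [{"x_index": a.coordinate.x_index, "y_index": a.coordinate.y_index,
          "stage_x": a.stage[0], "stage_y": a.stage[1]} for a in anchors]
    ).to_csv(path, index=False)
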