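"""Planar transform fitting shared by decode, navigate and register.

All routines work on ``(N, 2)`` arrays of (x, y) points in whatever
frame the caller uses; callers convert image (row, col) coordinates to
math (x=col, y=row or -row) frames themselves and document the choice.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "similarity_from_two_points",
    "umeyama",
    "fit_affine",
    "decompose_affine",
    "min_area_rect",
]


def similarity_from_two_points(src, dst, reflection: bool = False):
    """Exact similarity (scale, rotation, translation) from two point pairs.

    Returns a 2x3 matrix ``A`` with ``dst = A[:, :2] @ src + A[:, 2]``.
    With ``reflection`` the source is mirrored (y negated) first; two
    points cannot distinguish that case from a proper rotation, so the
    caller must decide.
    """
    src_orig = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src_orig.shape != (2, 2) or dst.shape != (2, 2):
        raise ValueError("expected exactly two 2-D points on each side")
    src = src_orig * np.array([1.0, -1.0]) if reflection else src_orig
    ds, dd = src[1] - src[0], dst[1] - dst[0]
    ns = math.hypot(*ds)
    if ns == 0 or math.hypot(*dd) == 0:
        raise DegenerateGeometryError("anchor points are coincident")
    s = math.hypot(*dd) / ns
    theta = math.atan2(dd[1], dd[0]) - math.atan2(ds[1], ds[0])
    c, si = math.cos(theta), math.sin(theta)
    lin = s * np.array([[c, -si], [si, c]])
    if reflection:
        lin = lin @ np.array([[1.0, 0.0], [0.0, -1.0]])
    t = dst[0] - lin @ src_orig[0]
    return np.column_stack([lin, t])


def umeyama(src, dst, allow_reflection: bool = False, force_reflection: bool = False):
    """Least-squares similarity fit (Kabsch/Umeyama) of src -> dst.

    Returns ``(matrix_2x3, scale, theta_rad, reflected)``.  By default
    the fit is constrained to a proper rotation; ``allow_reflection``
    lets the determinant choose, ``force_reflection`` demands a mirror.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    n = len(src)
    if n < 2:
        raise DegenerateGeometryError("need at least two points")
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = (xs ** 2).sum() / n
    if var_s == 0:
        raise DegenerateGeometryError("source points are coincident")
    cov = xd.T @ xs / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    det_sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    want_reflection = force_reflection or (allow_reflection and det_sign < 0)
    if (det_sign < 0) != want_reflection:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = (D * np.diag(S)).sum() / var_s
    t = mu_d - scale * R @ mu_s
    reflected = np.linalg.det(R) < 0
    theta = math.atan2(R[1, 0], R[0, 0]) if not reflected else math.atan2(R[1, 0], R[0, 0])
    return np.column_stack([scale * R, t]), scale, theta, bool(reflected)


def fit_affine(src, dst):
    """Least-squares 6-parameter affine fit; returns a 2x3 matrix."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError("affine fit needs at least three points")
    A = np.column_stack([src, np.ones(n)])
    if np.linalg.matrix_rank(A) < 3:
        raise DegenerateGeometryError("anchor points are collinear")
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    return coef.T  # 2x3


def decompose_affine(matrix):
    """Polar/SVD decomposition of a 2x3 affine map.

    Returns ``(sx, sy, theta_rad, shear, reflected)`` where sx >= sy are
    the singular values of the linear part (the anisotropic scale
    factors), theta the rotation of the polar factor, and shear the
    off-diagonal of the symmetric stretch normalized by sqrt(sx*sy).
    """
    L = np.asarray(matrix, float)[:, :2]
    U, D, Vt = np.linalg.svd(L)
    reflected = np.linalg.det(L) < 0
    R = U @ Vt
    if np.linalg.det(R) < 0:  # fold the mirror into the stretch factor
        U = U @ np.diag([1.0, -1.0])
        D = D.copy()
        R = U @ Vt
    theta = math.atan2(R[1, 0], R[0, 0])
    stretch = R.T @ L  # symmetric positive-definite part
    shear = stretch[0, 1] / math.sqrt(max(D[0] * D[1], 1e-300))
    return float(D[0]), float(D[1]), theta, float(shear), bool(reflected)


def min_area_rect(points):
    """Minimum-area bounding rectangle of a 2-D point set.

    Rotating-calipers over the convex hull.  Returns ``(corners, u, v)``
    where corners is a (4, 2) array in rectangle order and u, v are the
    unit edge directions (corners[1]-corners[0] and corners[3]-corners[0]).
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, float)
    if len(pts) < 3:
        lo, hi = pts.min(0), pts.max(0)
        corners = np.array([[lo[0], lo[1]], [hi[0], lo[1]],
                            [hi[0], hi[1]], [lo[0], hi[1]]])
        return corners, np.array([1.0, 0.0]), np.array([0.0, 1.0])
    try:
        hull = pts[ConvexHull(pts).vertices]
    except Exception:  # degenerate (collinear) input
        lo, hi = pts.min(0), pts.max(0)
        corners = np.array([[lo[0], lo[1]], [hi[0], lo[1]],
                            [hi[0], hi[1]], [lo[0], hi[1]]])
        return corners, np.array([1.0, 0.0]), np.array([0.0, 1.0])
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), math.pi / 2))
    best = None
    for a in angles:
        c, s = math.cos(a), math.sin(a)
        R = np.array([[c, s], [-s, c]])
        rot = hull @ R.T
        lo, hi = rot.min(0), rot.max(0)
        area = np.prod(hi - lo)
        if best is None or area < best[0]:
            best = (area, a, lo, hi)
    _, a, lo, hi = best
    c, s = math.cos(a), math.sin(a)
    R = np.array([[c, s], [-s, c]])
    corners_rot = np.array([[lo[0], lo[1]], [hi[0], lo[1]],
                            [hi[0], hi[1]], [lo[0], hi[1]]])
    corners = corners_rot @ R
    u = corners[1] - corners[0]
    v = corners[3] - corners[0]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    u = u / nu if nu > 0 else np.array([math.cos(a), math.sin(a)])
    v = v / nv if nv > 0 else np.array([-math.sin(a), math.cos(a)])
    return corners, u, v
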