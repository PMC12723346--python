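"""Fiducial co-registration tests."""

import math

import numpy as np
import pytest

from fidgrid import CameraModel, render
from fidgrid.codes import GridCoordinate
from fidgrid.decode import DetectedCode
from fidgrid.errors import InsufficientCorrespondenceError
from fidgrid.register import (
    CorrespondenceSet,
    ImageTransform,
    estimate_transform,
    match_by_code,
    registration_report,
    warp_and_overlay,
    warp_moving,
)


def _det(coord, pos, confidence=1.0):
    return DetectedCode(GridCoordinate(*coord), pos, 0.0, confidence)


def _apply_similarity(pos_rowcol, theta_deg, scale, t_colrow):
    th = math.radians(theta_deg)
    x, y = pos_rowcol[1], pos_rowcol[0]
    return (scale * (math.sin(th) * x + math.cos(th) * y) + t_colrow[1],
            scale * (math.cos(th) * x - math.sin(th) * y) + t_colrow[0])


class TestMatchByCode:
    def test_shared_codes_pair_up(self):
        fixed = [_det((i, 0), (10.0 * i, 5.0)) for i in range(5)]
        moving = [_det((i, 0), (3.0 * i, 50.0)) for i in range(1, 5)]
        corr = match_by_code(fixed, moving)
        assert len(corr.pairs) == 4
        assert corr.unmatched_fixed == ((0, 0),)

    def test_disjoint_sets_raise(self):
        fixed = [_det((0, 0), (0.0, 0.0)), _det((1, 0), (0.0, 10.0))]
        moving = [_det((5, 5), (0.0, 0.0)), _det((6, 5), (0.0, 10.0))]
        with pytest.raises(InsufficientCorrespondenceError):
            match_by_code(fixed, moving)

    def test_duplicate_keeps_higher_confidence(self, caplog):
        fixed = [_det((0, 0), (0.0, 0.0)), _det((1, 0), (0.0, 10.0)),
                 _det((1, 0), (99.0, 99.0), confidence=0.5)]
        moving = [_det((0, 0), (1.0, 1.0)), _det((1, 0), (1.0, 11.0))]
        with caplog.at_level("INFO", logger="fidgrid.register"):
            corr = match_by_code(fixed, moving)
        pair = [p for p in corr.pairs if p[0] == GridCoordinate(1, 0)][0]
        assert pair[1] == (0.0, 10.0)
        assert any("duplicate" in rec.message for rec in caplog.records)


class TestEstimateTransform:
    def test_known_similarity_recovered_exactly(self):
        fixed = [_det(c, p) for c, p in [((0, 0), (10.0, 20.0)),
                                         ((1, 0), (10.0, 120.0)),
                                         ((0, 1), (110.0, 20.0)),
                                         ((2, 2), (215.0, 230.0))]]
        moving = [_det((d.coordinate.x_index, d.coordinate.y_index),
                       _apply_similarity(d.position, 30.0, 0.8, (5.0, -7.0)))
                  for d in fixed]
        tf = estimate_transform(match_by_code(fixed, moving), "similarity")
        assert tf.rms_residual < 1e-9
        L = tf.matrix[:, :2]
        assert math.sqrt(abs(np.linalg.det(L))) == pytest.approx(1 / 0.8, rel=1e-9)
        mapped = tf.apply([m.position for m in moving])
        assert np.allclose(mapped, [f.position for f in fixed], atol=1e-9)

    def test_identity_correspondences(self):
        fixed = [_det((i, j), (50.0 * i, 50.0 * j))
                 for i in range(2) for j in range(2)]
        tf = estimate_transform(match_by_code(fixed, fixed), "similarity")
        assert np.allclose(tf.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)
        assert tf.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_noisy_affine_rms_matches_theory(self, rng):
        """RMS residual approximates sigma * sqrt(1 - dof/(2n))."""
        sigma, n = 0.5, 10
        A = np.array([[1.1, 0.08], [-0.05, 0.95]])
        rms_values = []
        for _ in range(200):
            moving_pts = rng.uniform(0, 400, (n, 2))
            fixed_pts = moving_pts @ A.T + [30.0, -12.0] + rng.normal(0, sigma, (n, 2))
            fixed = [_det((i, 0), tuple(fixed_pts[i])) for i in range(n)]
            moving = [_det((i, 0), tuple(moving_pts[i])) for i in range(n)]
            tf = estimate_transform(match_by_code(fixed, moving), "affine")
            rms_values.append(tf.rms_residual)
        # per-coordinate rms sigma*sqrt(1 - dof/2n); the reported rms is
        # a point distance, i.e. sqrt(2) times that
        expected = sigma * math.sqrt(2.0 * (1.0 - 6.0 / (2 * n)))
        assert np.mean(rms_values) == pytest.approx(expected, rel=0.1)

    def test_forward_and_backward_fits_are_inverse(self):
        fixed = [_det(c, p) for c, p in [((0, 0), (10.0, 20.0)),
                                         ((1, 0), (15.0, 140.0)),
                                         ((0, 1), (130.0, 30.0))]]
        moving = [_det((d.coordinate.x_index, d.coordinate.y_index),
                       _apply_similarity(d.position, -55.0, 1.4, (8.0, 3.0)))
                  for d in fixed]
        fwd = estimate_transform(match_by_code(fixed, moving), "similarity")
        rev = estimate_transform(
            CorrespondenceSet(pairs=tuple((p[0], p[2], p[1])
                                          for p in match_by_code(fixed, moving).pairs)),
            "similarity")
        prod = np.vstack([fwd.matrix, [0, 0, 1]]) @ np.vstack([rev.matrix, [0, 0, 1]])
        assert np.allclose(prod, np.eye(3), atol=1e-9)


class TestWarpAndOverlay:
    def test_identity_overlay_is_pixel_mean(self, rng):
        a = rng.uniform(0, 1, (64, 64))
        b = rng.uniform(0, 1, (64, 64))
        identity = ImageTransform("similarity",
                                  np.array([[1.0, 0, 0], [0, 1.0, 0]]), 0.0)
        comp = warp_and_overlay(a, b, identity, alpha=0.5)
        assert np.allclose(comp, (a + b) / 2, atol=1e-12)

    def test_alpha_endpoints(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        identity = ImageTransform("similarity",
                                  np.array([[1.0, 0, 0], [0, 1.0, 0]]), 0.0)
        assert np.allclose(warp_and_overlay(a, b, identity, alpha=0.0), a)
        assert np.allclose(warp_and_overlay(a, b, identity, alpha=1.0), b)

    def test_self_overlay_returns_image(self, rng):
        a = rng.uniform(0, 1, (48, 48))
        identity = ImageTransform("similarity",
                                  np.array([[1.0, 0, 0], [0, 1.0, 0]]), 0.0)
        assert np.allclose(warp_and_overlay(a, a, identity), a)

    def test_two_camera_renders_align_after_warp(self, small_layout):
        cam_f = CameraModel(pixel_size=1.0, image_size=(900, 900),
                            translation=(1250.0, 1250.0), blur_sigma=1.0)
        cam_m = CameraModel(pixel_size=1.25, image_size=(900, 900),
                            translation=(1250.0, 1250.0), rotation=20.0,
                            blur_sigma=1.0)
        fixed = render(small_layout, cam_f)
        moving = render(small_layout, cam_m)
        # ground-truth moving -> fixed transform from the two cameras
        th = math.radians(20.0)
        s = 1.25 / 1.0
        cc = (900 - 1) / 2
        R = s * np.array([[math.cos(th), math.sin(th)],
                          [-math.sin(th), math.cos(th)]])
        # in (x=col, y=row): fixed = R' @ (moving - c) + c with the row
        # axis flip folded in
        F = np.array([[1, 0], [0, -1.0]])
        L = F @ R @ F
        t = np.array([cc, cc]) - L @ [cc, cc]
        tf = ImageTransform("similarity", np.column_stack([L, t]), 0.0)
        warped = warp_moving(moving, tf, output_shape=fixed.shape, cval=0.5)
        interior = (slice(60, 840), slice(60, 840))
        code_px = fixed[interior] > 0.7
        assert code_px.sum() > 1000
        diff = np.abs(warped[interior] - fixed[interior])[code_px]
        assert diff.mean() < 0.02  # < 2% of dynamic range at code pixels


class TestRegistrationReport:
    def test_exact_fit_zero_residuals(self):
        fixed = [_det((i, j), (40.0 * i, 40.0 * j))
                 for i in range(2) for j in range(2)]
        corr = match_by_code(fixed, fixed)
        tf = estimate_transform(corr, "similarity")
        rep = registration_report(corr, tf, pixel_size=0.5)
        assert rep["max_px"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rep["residuals"]["residual_um"], 0.0)

    def test_corrupted_pair_is_max_residual(self):
        fixed = [_det((i, j), (40.0 * i, 40.0 * j))
                 for i in range(3) for j in range(3)]
        moving = list(fixed)
        moving[4] = _det((1, 1), (40.0 + 6.0, 40.0))
        corr = match_by_code(fixed, moving)
        tf = estimate_transform(corr, "similarity")
        rep = registration_report(corr, tf)
        worst = rep["residuals"].iloc[rep["residuals"]["residual_px"].idxmax()]
        assert (worst.x_index, worst.y_index) == (1, 1)

    def test_rms_tracks_noise(self, rng):
        sigma = 0.4
        fixed = [_det((i, j), (60.0 * i + rng.normal(0, sigma),
                               60.0 * j + rng.normal(0, sigma)))
                 for i in range(4) for j in range(4)]
        clean = [_det((i, j), (60.0 * i, 60.0 * j))
                 for i in range(4) for j in range(4)]
        corr = match_by_code(fixed, clean)
        tf = estimate_transform(corr, "similarity")
        rep = registration_report(corr, tf)
        assert rep["rms_px"] == pytest.approx(sigma * math.sqrt(2), rel=0.5)
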