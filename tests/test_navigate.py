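"""Stage-calibration (locator) tests."""

import math

import numpy as np
import pytest

from fidgrid.codes import GridCoordinate
from fidgrid.errors import DegenerateGeometryError, SingularTransformError
from fidgrid.navigate import (
    Anchor,
    anchors_from_csv,
    anchors_to_csv,
    calibrate,
    deformation_report,
    grid_to_stage,
    infer_reflection,
    stage_to_grid,
)

SPACING = 500.0


def _rot(theta_deg, scale=1.0):
    th = math.radians(theta_deg)
    return scale * np.array([[math.cos(th), -math.sin(th)],
                             [math.sin(th), math.cos(th)]])


def _anchor(coord, matrix, t):
    p = np.array(coord, float) * SPACING
    return Anchor(GridCoordinate(*coord), tuple(matrix @ p + np.asarray(t)))


class TestCalibrateSimilarity:
    def test_identity(self):
        m = calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 0), (500.0, 0.0))], SPACING)
        assert m.theta_deg == pytest.approx(0.0)
        assert m.scale == pytest.approx(1.0)
        assert tuple(m.matrix[:, 2]) == pytest.approx((0.0, 0.0))
        assert m.rms_residual == 0.0

    def test_quarter_turn(self):
        m = calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 0), (0.0, 500.0))], SPACING)
        assert m.theta_deg == pytest.approx(90.0)
        assert m.scale == pytest.approx(1.0)
        assert grid_to_stage(m, GridCoordinate(0, 1), SPACING) == \
            pytest.approx((-500.0, 0.0), abs=1e-9)

    def test_swollen_substrate_scale_factor(self):
        # 10% swelling read as the scale factor between two anchors
        th = math.radians(12.0)
        a = [Anchor(GridCoordinate(0, 0), (10.0, 20.0)),
             Anchor(GridCoordinate(2, 0),
                    (10.0 + 1100.0 * math.cos(th), 20.0 + 1100.0 * math.sin(th)))]
        m = calibrate(a, SPACING)
        assert m.scale == pytest.approx(1.1, rel=1e-9)
        assert m.theta_deg == pytest.approx(12.0, abs=1e-9)

    def test_two_anchor_scale_equals_distance_ratio(self, rng):
        for _ in range(20):
            M = _rot(rng.uniform(0, 360), rng.uniform(0.5, 2.0))
            t = rng.uniform(-1e4, 1e4, 2)
            c1, c2 = (1, 5), tuple(rng.integers(0, 60, 2))
            if tuple(c1) == tuple(c2):
                continue
            anchors = [_anchor(c1, M, t), _anchor(c2, M, t)]
            m = calibrate(anchors, SPACING)
            d_stage = math.dist(anchors[0].stage, anchors[1].stage)
            d_grid = SPACING * math.dist(c1, c2)
            assert m.scale == pytest.approx(d_stage / d_grid, rel=1e-12)

    def test_random_similarity_recovered_to_machine_precision(self, rng):
        for _ in range(100):
            theta = rng.uniform(0.0, 360.0)
            s = rng.uniform(0.5, 2.0)
            t = rng.uniform(-1e4, 1e4, 2)
            M = _rot(theta, s)
            c1 = tuple(rng.integers(0, 64, 2))
            c2 = tuple(rng.integers(0, 64, 2))
            if c1 == c2:
                continue
            m = calibrate([_anchor(c1, M, t), _anchor(c2, M, t)], SPACING)
            assert m.scale == pytest.approx(s, rel=1e-9)
            dtheta = (m.theta_deg - theta + 180.0) % 360.0 - 180.0
            assert abs(dtheta) < 1e-9 * 360.0
            assert np.allclose(m.matrix[:, 2], t, rtol=1e-9, atol=1e-6)

    def test_reflection_flag(self):
        mirror = np.array([[1.0, 0.0], [0.0, -1.0]])
        anchors = [_anchor((0, 0), mirror, (0, 0)), _anchor((2, 3), mirror, (0, 0)),
                   _anchor((5, 1), mirror, (0, 0))]
        m = calibrate(anchors, SPACING, reflection=True)
        assert m.reflection
        assert m.rms_residual == pytest.approx(0.0, abs=1e-9)
        pred = grid_to_stage(m, GridCoordinate(4, 4), SPACING)
        assert pred == pytest.approx((2000.0, -2000.0), abs=1e-6)

    def test_coincident_anchors_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 1), (0.0, 0.0))], SPACING)
        with pytest.raises(DegenerateGeometryError):
            calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(0, 0), (10.0, 0.0))], SPACING)


class TestStageToGrid:
    def test_lattice_point_has_zero_residual(self):
        m = calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 0), (500.0, 0.0))], SPACING)
        coord, resid = stage_to_grid(m, (1500.0, 2000.0), SPACING)
        assert coord == GridCoordinate(3, 4)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_perturbation_returns_residual(self):
        m = calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 0), (500.0, 0.0))], SPACING)
        coord, resid = stage_to_grid(m, (1500.0 + 125.0, 2000.0), SPACING)
        assert coord == GridCoordinate(3, 4)
        assert resid == pytest.approx(125.0)

    def test_midpoint_rounds_toward_lower_index(self):
        m = calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 0), (500.0, 0.0))], SPACING)
        coord, _ = stage_to_grid(m, (750.0, 250.0), SPACING)
        assert coord == GridCoordinate(1, 0)

    def test_roundtrip_identity_on_lattice(self, rng):
        M = _rot(77.0, 1.3)
        m = calibrate([_anchor((0, 0), M, (5.0, -3.0)),
                       _anchor((4, 9), M, (5.0, -3.0))], SPACING)
        for _ in range(20):
            c = GridCoordinate(*rng.integers(0, 64, 2))
            back, resid = stage_to_grid(m, grid_to_stage(m, c, SPACING), SPACING)
            assert back == c
            assert resid < 1e-6

    def test_singular_mapping_raises(self):
        m = calibrate([Anchor(GridCoordinate(0, 0), (0.0, 0.0)),
                       Anchor(GridCoordinate(1, 0), (500.0, 0.0))], SPACING)
        m.matrix = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(SingularTransformError):
            stage_to_grid(m, (10.0, 10.0), SPACING)


class TestAffineAndDeformation:
    def test_anisotropic_stretch_recovered(self):
        stretch = np.diag([1.10, 1.00])
        anchors = [_anchor(c, stretch, (0, 0))
                   for c in [(0, 0), (3, 1), (1, 4), (5, 5)]]
        m = calibrate(anchors, SPACING, model="affine")
        assert m.sx == pytest.approx(1.10, rel=1e-9)
        assert m.sy == pytest.approx(1.00, rel=1e-9)
        rep = deformation_report(m)
        assert rep["shear"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_rotation_decomposes_cleanly(self):
        M = _rot(25.0)
        anchors = [_anchor(c, M, (7.0, -2.0)) for c in [(0, 0), (4, 0), (0, 4)]]
        rep = deformation_report(calibrate(anchors, SPACING, model="affine"))
        assert rep["sx"] == pytest.approx(1.0, rel=1e-9)
        assert rep["sy"] == pytest.approx(1.0, rel=1e-9)
        assert rep["theta_deg"] == pytest.approx(25.0, abs=1e-9)

    def test_displaced_anchor_flagged_in_residuals(self):
        anchors = [_anchor(c, np.eye(2), (0, 0))
                   for c in [(0, 0), (6, 0), (0, 6), (6, 6), (3, 3)]]
        anchors[4] = Anchor(GridCoordinate(3, 3), (1550.0, 1500.0))
        m = calibrate(anchors, SPACING, model="affine")
        rep = deformation_report(m)
        resid = rep["residuals"]["residual"].to_numpy()
        assert resid.argmax() == 4
        assert resid[4] == pytest.approx(50.0, rel=0.25)
        assert resid[:4].max() < resid[4]

    def test_collinear_anchors_rejected(self):
        anchors = [_anchor(c, np.eye(2), (0, 0)) for c in [(0, 0), (1, 1), (3, 3)]]
        with pytest.raises(DegenerateGeometryError):
            calibrate(anchors, SPACING, model="affine")

    def test_piecewise_reproduces_every_anchor(self):
        rng = np.random.default_rng(3)
        coords = [(0, 0), (5, 0), (0, 5), (5, 5), (2, 3)]
        anchors = [Anchor(GridCoordinate(*c),
                          tuple(np.array(c) * SPACING * 1.05
                                + rng.normal(0, 20.0, 2)))
                   for c in coords]
        m = calibrate(anchors, SPACING, model="piecewise_affine")
        for a in anchors:
            assert grid_to_stage(m, a.coordinate, SPACING) == \
                pytest.approx(a.stage, abs=1e-6)

    def test_noisy_anchor_rmse_shrinks_as_sqrt_n(self, rng):
        """Similarity-parameter RMSE scales like sigma / sqrt(n)."""
        sigma = 5.0
        M = _rot(30.0, 1.2)
        t = np.array([100.0, -50.0])

        def rmse(n, reps=300):
            err = []
            side = int(math.ceil(math.sqrt(n)))
            coords = [(i, j) for i in range(side) for j in range(side)][:n]
            for _ in range(reps):
                anchors = [
                    Anchor(GridCoordinate(*c),
                           tuple(M @ (np.array(c, float) * SPACING) + t
                                 + rng.normal(0, sigma, 2)))
                    for c in coords]
                m = calibrate(anchors, SPACING)
                err.append(np.hypot(*(m.matrix[:, 2] - t)))
            return float(np.sqrt(np.mean(np.square(err)))), float(np.mean(err))

        r4, bias4 = rmse(4)
        r16, _ = rmse(16)
        r64, _ = rmse(64)
        assert r4 / r16 == pytest.approx(2.0, rel=0.35)
        assert r16 / r64 == pytest.approx(2.0, rel=0.35)
        assert bias4 < 4.0 * sigma  # no systematic drift

    def test_infer_reflection_votes(self):
        class Det:
            def __init__(self, m):
                self.mirrored = m

        assert infer_reflection([Det(True), Det(True), Det(False)])
        assert not infer_reflection([Det(False), Det(False)])
        with pytest.raises(ValueError):
            infer_reflection([])


class TestAnchorIO:
    def test_csv_roundtrip(self, tmp_path):
        anchors = [Anchor(GridCoordinate(1, 2), (10.5, -3.25)),
                   Anchor(GridCoordinate(7, 0), (990.0, 410.0))]
        path = tmp_path / "anchors.csv"
        anchors_to_csv(anchors, path)
        assert anchors_from_csv(path) == anchors
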