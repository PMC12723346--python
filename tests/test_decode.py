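"""Machine-vision decoding tests against the renderer's ground truth."""

import math

import numpy as np
import pytest

from fidgrid import (
    CameraModel,
    DecodeHints,
    DetectedCode,
    detect_codes,
    neighbor_consistency_filter,
    render,
)
from fidgrid.codes import GridCoordinate, GridSpec, footprint
from fidgrid.decode import (
    decode_rectified_patch,
    detections_from_csv,
    detections_to_csv,
)
from fidgrid.layout import GridLayout, generate_grid
from fidgrid.synthimg import ground_truth


def _match(detections, truth):
    """Position errors (px) of correctly decoded truth rows."""
    errors = {}
    for det in detections:
        rows = truth[(truth.x_index == det.coordinate.x_index)
                     & (truth.y_index == det.coordinate.y_index)]
        if len(rows):
            row = rows.iloc[0]
            errors[(det.coordinate.x_index, det.coordinate.y_index)] = math.hypot(
                det.position[0] - row.px_row, det.position[1] - row.px_col)
    return errors


class TestDetectCodes:
    def test_clean_field_decodes_completely(self, small_layout, centered_camera):
        cam = centered_camera(blur_sigma=2.0)
        img = render(small_layout, cam)
        truth = ground_truth(small_layout, cam)
        hints = DecodeHints(spec=small_layout.spec, approx_pixel_size=1.2)
        dets = detect_codes(img, hints)
        errors = _match(dets, truth)
        assert len(errors) == len(truth) > 4
        assert max(errors.values()) < 1.0

    def test_half_turn_is_disambiguated_by_the_align_mark(
            self, small_layout, centered_camera):
        cam0 = centered_camera(blur_sigma=2.0)
        cam180 = centered_camera(blur_sigma=2.0, rotation=180.0)
        hints = DecodeHints(spec=small_layout.spec, approx_pixel_size=1.2)
        coords0 = {(d.coordinate.x_index, d.coordinate.y_index)
                   for d in detect_codes(render(small_layout, cam0), hints)}
        dets180 = detect_codes(render(small_layout, cam180), hints)
        coords180 = {(d.coordinate.x_index, d.coordinate.y_index)
                     for d in dets180}
        assert coords0 == coords180
        for det in dets180:
            assert abs(((det.orientation_deg - 180.0) + 180) % 360 - 180) < 2.0

    def test_blank_image_yields_empty_list(self, binary_spec):
        hints = DecodeHints(spec=binary_spec, approx_pixel_size=1.0)
        assert detect_codes(np.full((256, 256), 0.5), hints) == []
        noise = 0.5 + np.random.default_rng(0).normal(0, 0.02, (256, 256))
        assert detect_codes(noise, hints) == []

    def test_gross_scale_hint_logs_and_returns_empty(
            self, small_layout, centered_camera, caplog):
        img = render(small_layout, centered_camera())
        hints = DecodeHints(spec=small_layout.spec, approx_pixel_size=1.2 * 3.5)
        with caplog.at_level("WARNING", logger="fidgrid.decode"):
            assert detect_codes(img, hints) == []
        assert any("disagrees" in rec.message for rec in caplog.records)

    def test_polarity_auto_matches_explicit(self, small_layout, centered_camera):
        cam = centered_camera(polarity="dark_features", blur_sigma=1.0)
        img = render(small_layout, cam)
        auto = detect_codes(img, DecodeHints(spec=small_layout.spec,
                                             approx_pixel_size=1.2))
        explicit = detect_codes(img, DecodeHints(spec=small_layout.spec,
                                                 approx_pixel_size=1.2,
                                                 polarity="dark_features"))
        assert {(d.coordinate.x_index, d.coordinate.y_index) for d in auto} \
            == {(d.coordinate.x_index, d.coordinate.y_index) for d in explicit}

    def test_ternary_field_decodes(self, ternary_spec):
        layout = generate_grid(ternary_spec, (3000.0, 3000.0))
        cam = CameraModel(pixel_size=1.0, image_size=(1400, 1400),
                          rotation=25.0, translation=(1250.0, 1250.0),
                          blur_sigma=1.0, noise_sigma=0.01, seed=2)
        img = render(layout, cam)
        truth = ground_truth(layout, cam)
        hints = DecodeHints(spec=ternary_spec, approx_pixel_size=1.0)
        errors = _match(neighbor_consistency_filter(detect_codes(img, hints),
                                                    hints), truth)
        assert len(errors) == len(truth) > 3

    def test_scale_sweep_single_parameterization(self, binary_spec):
        """One decoder configuration reads a ten-fold pixel-size range."""
        layout = generate_grid(binary_spec, (6000.0, 6000.0))
        for f_px in (4.0, 12.0, 40.0):
            ps = binary_spec.feature_size / f_px
            cam = CameraModel(pixel_size=ps, image_size=(1024, 1024),
                              rotation=30.0,
                              translation=(2750.0, 2750.0),
                              blur_sigma=1.0, noise_sigma=0.01, seed=4)
            img = render(layout, cam)
            truth = ground_truth(layout, cam)
            hints = DecodeHints(spec=binary_spec, approx_pixel_size=ps)
            errors = _match(detect_codes(img, hints), truth)
            assert len(errors) == len(truth), f_px


def _synthetic_detection(coord, spacing_px, origin=(100.0, 100.0),
                         confidence=1.0):
    return DetectedCode(
        coordinate=GridCoordinate(*coord),
        position=(origin[0] - coord[1] * spacing_px,
                  origin[1] + coord[0] * spacing_px),
        orientation_deg=0.0,
        confidence=confidence,
        scale_px_per_um=spacing_px / 500.0,
        margin=1.0,
    )


class TestNeighborConsistencyFilter:
    def setup_method(self):
        self.spec = GridSpec(feature_size=10.0, spacing=500.0)
        self.hints = DecodeHints(spec=self.spec, approx_pixel_size=5.0)

    def test_consistent_set_unchanged(self):
        dets = [_synthetic_detection((x, y), 100.0)
                for x in range(3) for y in range(3)]
        assert neighbor_consistency_filter(dets, self.hints) == dets

    def test_single_corrupted_coordinate_removed(self):
        dets = [_synthetic_detection((x, y), 100.0)
                for x in range(3) for y in range(3)]
        bad = _synthetic_detection((2, 2), 100.0)
        # single-bit corruption: coordinate says (6, 2) but the code sits
        # at the (2, 2) lattice position
        corrupted = DetectedCode(coordinate=GridCoordinate(6, 2),
                                 position=bad.position, orientation_deg=0.0,
                                 confidence=0.9,
                                 scale_px_per_um=bad.scale_px_per_um,
                                 margin=0.9)
        kept = neighbor_consistency_filter(dets[:-1] + [corrupted], self.hints)
        assert corrupted not in kept
        assert len(kept) == 8

    def test_inconsistent_pair_keeps_higher_confidence(self):
        a = _synthetic_detection((0, 0), 100.0, confidence=0.95)
        b = DetectedCode(coordinate=GridCoordinate(5, 5),
                         position=(90.0, 110.0), orientation_deg=0.0,
                         confidence=0.85, scale_px_per_um=0.2, margin=0.85)
        kept = neighbor_consistency_filter([a, b], self.hints)
        assert kept == [a]

    def test_singleton_passes_unchanged(self):
        det = _synthetic_detection((3, 4), 80.0)
        assert neighbor_consistency_filter([det], self.hints) == [det]


class TestRectifiedPatch:
    @pytest.mark.parametrize("scheme,spacing", [("binary", 500.0),
                                                ("ternary", 500.0),
                                                ("decimal", 600.0),
                                                ("planet", 1000.0)])
    def test_upright_patch_reads_back(self, scheme, spacing):
        spec = GridSpec(scheme=scheme, feature_size=10.0, spacing=spacing)
        coord = GridCoordinate(47 % spec.addressable, 58 % spec.addressable)
        fw, fh = footprint(spec)
        layout = GridLayout(spec=spec, extent=(fw, fh),
                            placements=((coord, (0.0, 0.0)),))
        ps = 0.5
        cam = CameraModel(pixel_size=ps,
                          image_size=(int(fh / ps), int(fw / ps)),
                          translation=(fw / 2 - ps / 2, fh / 2 - ps / 2),
                          blur_sigma=0.5)
        patch = render(layout, cam)
        assert decode_rectified_patch(patch, spec, ps) == coord


class TestDetectionTables:
    def test_csv_roundtrip(self, tmp_path):
        dets = [_synthetic_detection((x, 2 * x), 90.0, confidence=0.9 + 0.01 * x)
                for x in range(4)]
        path = tmp_path / "dets.csv"
        detections_to_csv(dets, path)
        back = detections_from_csv(path)
        assert [d.coordinate for d in back] == [d.coordinate for d in dets]
        assert np.allclose([d.position for d in back],
                           [d.position for d in dets])
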