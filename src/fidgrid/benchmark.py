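"""Randomized decoder evaluation against the renderer's ground truth.

Each scene images a fixed interior region of a binary grid (10 um
features, 500 um pitch — the reference design) under conditions drawn
once per scene:

* pixel scale log-uniform over a ten-fold range, 4 to 40 px per
  feature;
* in-plane rotation uniform over 0-360 degrees;
* Gaussian PSF sigma uniform up to half a feature;
* additive noise sigma uniform up to 5% of the dynamic range;
* either contrast polarity (brightfield-like or darkfield/SEM-like);
* the decoder's pixel-size hint deliberately mis-stated by up to 30%.

Camera centres stay three pitches inside the grid boundary, as in
practice where the coded substrate is much larger than any field of
view.  Recall counts fully visible codes recovered with the correct
coordinate; precision checks every reported detection against the
code actually present at its (back-projected) position, so correctly
decoded partially visible codes are not counted as errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codes import GridSpec
from .decode import DecodeHints, detect_codes, neighbor_consistency_filter
from .layout import generate_grid
from .synthimg import CameraModel, ground_truth, render

__all__ = ["SceneResult", "sample_camera", "evaluate_scene", "decoder_benchmark"]

_SPEC = GridSpec(scheme="binary", feature_size=10.0, spacing=500.0)
_EXTENT = (6000.0, 6000.0)


@dataclass
class SceneResult:
    visible: int
    recalled: int
    wrong: int  # detections contradicting the code at their position
    detections: int
    camera: CameraModel


def sample_camera(rng: np.random.Generator, image_px: int = 1024) -> CameraModel:
    f_px = math.exp(rng.uniform(math.log(4.0), math.log(40.0)))
    return CameraModel(
        pixel_size=_SPEC.feature_size / f_px,
        image_size=(image_px, image_px),
        rotation=float(rng.uniform(0.0, 360.0)),
        translation=tuple(rng.uniform(1500.0, 4500.0, size=2)),
        polarity=("bright_features", "dark_features")[int(rng.integers(2))],
        blur_sigma=float(rng.uniform(0.0, 0.5 * _SPEC.feature_size)),
        noise_sigma=float(rng.uniform(0.0, 0.05)),
        seed=int(rng.integers(2 ** 31)),
    )


def _pixel_to_phys(camera: CameraModel, pos_rowcol) -> np.ndarray:
    rows, cols = camera.image_size
    r, c = pos_rowcol
    ux = (c - (cols - 1) / 2.0) * camera.pixel_size
    uy = ((rows - 1) / 2.0 - r) * camera.pixel_size
    th = math.radians(camera.rotation)
    x = math.cos(th) * ux + math.sin(th) * uy
    y = -math.sin(th) * ux + math.cos(th) * uy
    return np.asarray(camera.translation) + (x, y)


def evaluate_scene(layout, camera: CameraModel, rng: np.random.Generator) -> SceneResult:
    img = render(layout, camera)
    truth = ground_truth(layout, camera)
    hint_error = float(rng.uniform(0.75, 1.3))
    hints = DecodeHints(spec=layout.spec,
                        approx_pixel_size=camera.pixel_size * hint_error)
    detections = neighbor_consistency_filter(detect_codes(img, hints), hints)

    spacing = layout.spec.spacing
    sites = {(c.x_index, c.y_index) for c, _ in layout.placements}
    wrong = 0
    found = {}
    for det in detections:
        phys = _pixel_to_phys(camera, det.position)
        site = (int(round(phys[0] / spacing)), int(round(phys[1] / spacing)))
        offset = float(np.linalg.norm(phys - np.array(site) * spacing))
        key = (det.coordinate.x_index, det.coordinate.y_index)
        if site in sites and key == site and offset < 0.25 * spacing:
            found[key] = det
        else:
            wrong += 1
    recalled = sum(1 for row in truth.itertuples()
                   if (row.x_index, row.y_index) in found)
    return SceneResult(visible=len(truth), recalled=recalled, wrong=wrong,
                       detections=len(detections), camera=camera)


def decoder_benchmark(n_scenes: int = 100, seed: int = 0,
                      image_px: int = 1024) -> dict:
    """Aggregate recall/precision over ``n_scenes`` random scenes."""
    rng = np.random.default_rng(seed)
    layout = generate_grid(_SPEC, _EXTENT)
    visible = recalled = wrong = detections = 0
    results = []
    for _ in range(n_scenes):
        camera = sample_camera(rng, image_px=image_px)
        res = evaluate_scene(layout, camera, rng)
        results.append(res)
        visible += res.visible
        recalled += res.recalled
        wrong += res.wrong
        detections += res.detections
    return {
        "n_scenes": n_scenes,
        "visible_codes": visible,
        "recalled": recalled,
        "recall": recalled / visible if visible else float("nan"),
        "wrong_detections": wrong,
        "precision": ((detections - wrong) / detections
                      if detections else float("nan")),
        "scenes": results,
    }
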