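# Methods

This note records the models, conventions, parameter choices and known
limitations behind `fidgrid`, module by module.

## Coding schemes and geometry

A code symbol embeds its own integer grid address `(x, y)` as axis-aligned
rectangles in a local frame (micrometres, origin at the align-mark outer
corner, y up). The governing parameter is the minimum feature size `f` — the
side of a single bit square and the smallest fabricated dimension.

**Binary** (reference design): a `(n+1)×(n+1)` cell lattice of cell side
`f`, default `n = 6` bits per axis (64 × 64 addressable sites). Cell (0,0)
is the always-filled align mark; cells (1..n, 0) carry the x bits and
(0, 1..n) the y bits. The most significant bit sits in the cell adjacent to
the align mark, so a human reading an electron micrograph from the align
mark outward reads the printed binary number directly. The footprint is
`7f × 7f` at the defaults — six bit cells plus the align cell per side.
Filled cells are squares of side `fill_factor × f` (default 1.0; adjacent
bits may merge visually, which the decoder's cell-centre sampling ignores).

**Ternary**: same lattice; a trit is encoded in bar thickness — empty,
half-width bar (`f/2`), or full square — giving 729 addresses per axis from
the same footprint. Thickness levels 0 / ½ / 1 maximize separability at the
fabrication limit.

**Decimal**: rectilinear seven-segment digits (stroke `f`, glyph `3f × 5f`),
chosen over curved numerals because curves challenge both machine vision
and microscale pattern transfer. Two digit rows (x above y) sit above a
full-width align bar — the only element wider than a glyph, hence
unambiguous. Footprint `(4n−1)f × 13f` for `n` digits per axis.

**PLANET-style**: each digit is five bars (two tall of height `5f`, three
short of `2f`; bar width `f`, gap `f`) using the postal weight table
7-4-2-1-0 (weight sum 11 encodes 0); the x then y digit strings are
delimited by two full-height frame bars serving as align marks and
measurement points. No checksum digit by default (an application-level
concern, not part of the geometry).

Design properties worth stating precisely:

* *Rotation chirality.* For any code with ink on **both** arms, no proper
  rotation maps it onto another (or the same) canonical code: arms meet at
  the unique align corner and the opposite lattice corner is always empty.
  This is what lets the decoder fix orientation from a single marker.
* *The single-arm exception.* A code with one empty bit vector (x = 0 or
  y = 0) is a line of squares; a 180° turn re-reads it as another valid
  single-arm code (e.g. binary (5, 0) flips into (17, 0)). Such patterns —
  and only such patterns — are inherently orientation-ambiguous in
  isolation. The decoder resolves them against neighbouring detections and
  otherwise down-weights them below the reporting threshold.
* *Mirror symmetry.* The L layout maps onto the code of the transposed
  coordinate under a diagonal mirror, per code *and* globally. A mirrored
  view (imaging through the substrate) is therefore indistinguishable from
  a proper view of transposed coordinates; handedness is a session-level
  declaration (`DecodeHints.assume_mirrored`, default proper), exactly like
  the reflection flag of the two-anchor calibration.

## Layout and mask export

The inter-marker pitch is sized by the most constrained ("bottleneck")
instrument: the largest multiple `S` of a quantization step (default
100 µm) with `S + footprint ≤ FOV` guarantees one fully visible code in any
axis-aligned FOV-square window. The reference design (600 µm confocal FOV,
80 µm binary code) yields `S = 500 µm`, i.e. 4 markers/mm². Marker density
is `(1000/S)²` per mm². Grid sites anchor the align corner at
`(i·S, j·S)`; every site whose footprint fits the requested extent is
populated with its unique coordinate.

GDSII export writes one structure per code referenced from a single top
cell (`MUGRID`), database unit 1 nm, user unit 1 µm, default layer/datatype
1/0. The stream writer/reader is a purpose-built minimal implementation
(HEADER/UNITS/BGNSTR/BOUNDARY/SREF records, exact excess-64 base-16 reals
via rational arithmetic); a write→read cycle reproduces every rectangle to
the nanometre, which the tests audit. SVG previews and a JSON layout
serialization round out the interchange formats.

## Synthetic imaging model

The renderer is the package's fixture generator — a stand-in for real
micrographs, synthetic by construction. Each rectangle is deformed (see
below), mapped by the camera similarity (pixel size `p`, in-plane rotation,
translation of the image centre), rasterized with area-weighted
anti-aliasing (4×4 supersampling of a half-plane test), convolved with an
isotropic Gaussian PSF proxy, polarity-encoded and corrupted with additive
Gaussian noise (deterministic per seed). Feature intensity is
`background ± contrast` (defaults 0.5 ± 0.45 of the dynamic range), so
flipping polarity mirrors the image about the background exactly —
brightfield-like (dark features) versus darkfield/secondary-electron-like
(bright features).

Conventions: the image row axis is the negative physical y axis (standard
raster order); pixel centres sit at integer indices; `ground_truth` reports
the align-corner sub-pixel (row, col) and the in-image angle of the grid +x
axis for every code whose footprint lies fully in frame.

Deformation models act in the physical frame about the layout origin:
uniform scale, anisotropic scale `(sx, sy)`, or a table of rectangular
regions with per-region affine maps (local, non-uniform warping). What the
renderer does *not* emulate: modality-specific optics (defocus, charging,
shading), shot noise, occluding cells, or z-structure. Passing tests
demonstrate geometric and photometric robustness within that envelope, not
robustness to those effects.

## Decoder

The pipeline (binary/ternary):

1. *Polarity and thresholds.* A cheap percentile test picks the feature
   polarity (or tries both). Because ink occupies a tiny fraction of a
   frame, global Otsu can split the noise instead of the signal; instead, a
   matched-filter detection pass (Gaussian smooth of ≈ 0.3 feature) with a
   MAD-based noise floor finds ink, and a half-amplitude threshold between
   the median background and a high-percentile ink-core level (the
   detection mask includes wide PSF skirts that must not drag the
   threshold down) defines the reading mask.
2. *Self-calibration.* The stroke width (median over components of twice
   the distance-transform maximum) estimates the feature size in pixels,
   cross-checked against the hinted pixel size (±50%, with allowance for
   blur inflation; a gross mismatch logs a diagnostic and reports nothing).
3. *Clustering and axes.* Components cluster into code candidates (intra-
   code gaps are at most five features; codes sit many footprints apart).
   Candidate lattice axes come from the minimum-area bounding rectangle
   *and* from pairwise component-centroid directions — centroids sit
   exactly on the two arm lines, so every pair involving the align blob
   points along an axis even when heavy blur rounds the blobs.
4. *Lattice search.* For each axis candidate, rectangle corner and axis
   order (mirror twins excluded per the declared handedness), candidate
   cell sizes are enumerated from the ink-span divided by small integers
   (arm spans are exact multiples of `f`), then refined over scale and
   corner offset.
5. *Reading.* Cell centres are sampled (3×3 window) on the background-
   subtracted intensity and classified with a blur-aware linear mixing
   model `v_i ≈ z0·w_i + z1·(w_{i−1}+w_{i+1})`, alternating a two-parameter
   least-squares fit with re-classification. This stays stable from sharp
   images up to a PSF of half a feature. Hypothesis validity requires a
   solid align cell, an empty interior, all cluster ink inside the lattice,
   no ink far from decoded cells at half-cell probing, and full-cell
   coverage for solid symbols (a square is exactly one feature wide, which
   rejects mis-scaled lattices).
6. *Deconvolution re-read.* The fitted mixing ratio `z1/z0` maps through
   the Gaussian-PSF relation to a width estimate; when it implies a heavy
   PSF the frame is Wiener-deconvolved at that width (and at 0.7× it, since
   blur inflates the width estimate) and re-read; readings of the same spot
   compete on their raw margin.
7. *Consensus and confidence.* Across clusters, pairs of candidate
   readings seed grid→image similarities; the transform explaining the
   most clusters (position, scale *and* orientation must agree — a set of
   orientation-free line misreads can otherwise fake a rotated consensus,
   and a pair always trivially explains itself, so at least three
   supporting clusters are required) adjudicates each cluster. Uncertifiable
   readings — rival candidates of similar margin, empty-arm patterns, or
   clusters touching the frame edge (a truncated code can read as a valid
   shorter pattern) — are down-weighted below the default reporting
   threshold unless the consensus corroborates them. Sub-pixel positions
   come from a similarity refit of measured component centroids against the
   decoded geometry's expected centroids (centroids of blurred ink are
   unbiased under a symmetric PSF), giving ≈ 0.02–0.2 px accuracy.
8. *Filtering.* `neighbor_consistency_filter` keeps the largest subset
   whose per-detection frames agree on one grid→image similarity within a
   quarter pitch — single-bit corruptions displace a detection by a full
   pitch and are removed.

Decimal and PLANET symbols have full geometry and logical codecs plus
rectified-patch readers (seven-segment / tall-bar presence tests on an
upright crop); the full-image detector covers the lattice schemes, whose
align-corner-plus-two-arms structure its candidate search exploits.

**Evaluation protocol** (`fidgrid.benchmark`): scenes image the interior of
a 12×12 reference grid (10 µm features, 500 µm pitch) at 1024² px with, per
scene: pixel scale log-uniform over 4–40 px/feature, rotation uniform
0–360°, PSF sigma uniform 0–0.5 feature, noise sigma uniform 0–5%, either
polarity, and the decoder's pixel-size hint mis-stated by up to ±30%.
Recall counts fully visible codes recovered with the correct coordinate;
precision validates every detection against the code actually present at
its back-projected position (so a correctly read, partially visible code is
not an error). The acceptance bar — ≥ 99% recall, no wrong coordinate after
filtering over 100 scenes — is this package's own quality gate for the
classical-vision decoder; real micrographs add effects (occlusion,
defocus, fabrication defects) outside this protocol.

## Stage navigation

Grid physical positions are `coordinate × pitch` (µm); stage units are
declared per session and never silently converted. Two anchors determine
the similarity exactly: the scale factor is the stage-to-grid distance
ratio — the substrate-deformation metric — and the rotation follows from
the angle between the anchor baselines; the residual is zero by
construction. Two anchors cannot distinguish a proper rotation from a
mirrored view, so reflection is an explicit flag. More anchors are fitted
in least squares (Umeyama for similarity, linear for affine); the affine
linear part's singular values are the per-axis anisotropic scale factors
and its polar decomposition supplies rotation and shear, with a per-anchor
residual table for outlier spotting. Four or more anchors support a
piecewise-affine (Delaunay) model that interpolates every anchor exactly —
local deformation compensation; outside the anchor hull it falls back to
the global affine summary. Inverse lookup divides by the pitch and rounds,
half toward the lower index (a documented tie-break).

## Co-registration

Detections from two modalities are matched purely by decoded coordinate —
globally unique fiducials need no descriptor matching; duplicates keep the
higher-confidence detection, and fewer than two shared codes is an error.
The moving→fixed pixel transform is a least-squares similarity (default —
rotation plus scaling covers magnification and rigid pose differences) or
affine (anisotropic shrinkage), exact at the minimal configuration, with
RMS residual reported otherwise. Warping is bilinear (nearest-neighbour
available for label images) and the composite is
`(1−α)·fixed + α·warped` with α = 0.5 by default — the classic
half-transparency overlay — plus an optional RGB tint mode for
fluorescence-on-SEM composites. One fitted transform is meant to be applied
to all co-acquired channels of the moving stack, which assumes those
channels are pixel-registered at acquisition. Intensity-based refinement is
deliberately absent: the method is purely fiducial/geometric.

## Numerical choices and problem sizes

* Transform fits use SVD (Umeyama) and `lstsq`; recovery from exact
  anchors is asserted to 1e-9 relative.
* Renderer anti-aliasing: 4×4 supersampling (coverage quantized to 1/16
  per sample cell); blur and noise applied after rasterization.
* Decoder tolerances: quarter-pitch consistency radius; 20° / 22%
  orientation/scale agreement bands in the consensus; confidence is the
  worst-cell margin normalized by 0.35 of the level gap, capped at 1, and
  scaled by 0.4 when a reading is uncertifiable (defaults drop it at the
  0.8 reporting threshold).
* Test problem sizes: the decoder benchmark runs 100 scenes at 1024² px
  (roughly 300–800 visible codes); Monte-Carlo calibrations use 1000
  replicates; the registration demonstration uses 1400² px frames with
  4–12 shared fiducials. These sizes exercise every code path at
  full-grid realism while keeping the default suite quick to run.

## Known limitations

* Reflection handedness cannot be inferred from lattice codes (diagonal
  mirror symmetry, above); it must be declared.
* Empty-arm (x = 0 or y = 0) codes and frame-edge codes are reported only
  when corroborated by neighbours.
* The decoder assumes roughly uniform illumination across a frame (global
  reading threshold); strong shading would need a local-threshold variant.
* Decimal/PLANET full-image detection is not implemented (rectified-patch
  readers only).
* z-dimension calibration is out of scope: code heights of a few hundred
  nanometres carry too little depth range to calibrate focus.
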