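# Methods

This note documents the measurement model behind `laryngometry`, the
conventions it commits to where clinical practice is not standardized, what
the synthetic phantoms do and do not emulate, and the package's numerical
choices and known limitations.

## Metric calibration from laser fiducials

**Dot pair.** Two parallel laser beams (515 nm, separation `s` = 1 mm by
default) project as two bright green dots. Detection thresholds a
green-dominance map `G − (R+B)/2` (median-filtered, threshold 0.25 × max),
labels connected components, ranks them by integrated intensity and takes
the two brightest. Centroids are intensity-weighted and then refined by a
least-squares 2-D Gaussian fit on an 17 × 17 px patch, giving centimetre-
grade accuracy at typical working distances (sub-0.02 px centroid error on
phantoms). The scale is `mm_per_px = s / ‖c₂ − c₁‖`. The dot separation is
treated as depth-independent over the working range; this is a stated
approximation of the rig, not a derived property.

**Line triple and depth.** The oropharyngeal module projects two parallel
reference lines (separation 10 mm by default — this also provides the
scene's metric scale) plus one beam tilted by θ = 8.5°. The geometric model
adopted here: the tilted beam appears tilted by θ in the image plane *and*
its intersection with a surface farther from the scope by `d` is laterally
displaced by `d·tan θ` (in true mm) relative to a nearer surface. Whether
the clinical device tilts in the image plane or toward the optical axis is
not observable from stills; this lateral-offset-proportional-to-depth model
is the package's normative convention.

Detection fits a total-least-squares line to every connected laser
component and merges components into *beams* when they are parallel within
2° and laterally closer than 120 px (a beam is split into one component per
surface by the occluding edge at a depth discontinuity). Exactly three
beams must emerge; the pair with minimal mutual angle is the reference
pair. Offsets of the tilted beam from the left reference line are evaluated
by extrapolating each surface's segment to the surface-boundary row —
evaluating both at the same row cancels the in-plane tilt drift, so the
offset difference isolates the depth jump, and

    depth = (far_offset_mm − near_offset_mm) / tan θ.

## Morphometry conventions

* **Fold length** = caliper extent of the fold polygon's vertices projected
  on its area-weighted major principal axis (second-moment integrals over
  the polygon interior, so the axis does not depend on vertex density).
* **Fold width** = total chord length of the polygon cut perpendicular to
  that axis through the 50%-length point.
* **Areas** are vertex-exact shoelace areas × `mm_per_px²`. Glottic area is
  the area of the annotated glottal-gap polygon (folds excluded); CSAOI is
  the annotated inlet polygon using the oropharyngeal scene's line-derived
  scale. Vocal area is reported per fold.
* **Vocal angle** = interior angle at the anterior commissure between rays
  to the two vocal processes.
* **Aggregation**: repeated evaluations (clinically ≥ 3) combine by
  fieldwise maximum, each field maximized independently.
* **Percent change**: post as a percentage of the pre baseline
  (pre ≡ 100%); a signed variant `100·(post−pre)/pre` is available.

All vertex-geometry steps are exactly invariant under rotation/translation;
raster-dependent steps (fiducial detection) are invariant to within ~1%.

## Color and texture features

* "Hue" features are the region's mean R, G, B intensities — channel-wise
  analysis, *not* the HSV hue angle.
* CIELab is computed in two stages, sRGB → XYZ (D65) → Lab. The Lab stage
  normalizes by the exact sRGB matrix white so grays sit exactly on the
  neutral axis (a\* = b\* = 0) and white maps to (100, 0, 0). The region's
  Lab is that of its mean RGB (stable for small regions); per-pixel Lab
  averaging is available via `per_pixel_lab=True`.
* Region membership uses the even-odd rule on pixel centers (0-based
  coordinates, origin top-left, x rightward, y downward).
* GLCM: intensities are quantized into `levels` = 8 equal-width bins over
  the *fixed* range [0, 1] (not the region's min-max, so texture amplitude
  differences between images are preserved), pairs accumulated for offsets
  {(0,1), (1,0), (1,1), (1,−1)}, symmetrized, normalized to sum 1 per
  offset; only pairs with both pixels inside the region count. Features are
  computed per offset and averaged. Energy is Σp² (not its square root).
  Degenerate correlation (zero marginal variance) is defined as 1: a
  perfectly homogeneous region is perfectly predictable. GLCM is computed
  per color channel by default (`grayscale=True` switches to luminance).

## The function index

Per image/region three raw features are taken: a\* (the red-green
coordinate — inflammation is a "trend to red"), GLCM contrast and GLCM
correlation from the R channel (the most discriminative channel for mucosal
erythema; configurable). Each is min-max normalized across the cohort —
the index is therefore a *cohort-relative* score, defined only for cohorts
of ≥ 2 images; a constant feature normalizes to all-zeros — and combined as

    index = 0.35·color² + 0.34·contrast² + 0.32·correlation²,

bounded in [0, 1.01] and monotone non-decreasing in each normalized
feature. Weights are configuration with those defaults. ROC analysis sweeps
the unique score values (trapezoidal AUC = Mann-Whitney statistic, ties
count half); the operating point maximizes Youden's J with ties broken
toward higher specificity, and `score ≥ cutoff` predicts positive
(post-operative/inflamed). Score orientation is reported as-is — an AUC
below 0.5 is not silently flipped.

## What the phantoms emulate

Laryngeal scenes (default 640 × 480 px at 0.05 mm/px) lay out a lens-shaped
glottal gap (12 × 3 mm), flanking 3 mm fold bands, a posterior
interarytenoid band, landmarks, and the dot pair at sub-pixel positions.
Mucosa is a flesh-tone base plus smoothed Gaussian noise (SD 0.06,
smoothing 1.2 px). The `inflammation` parameter in [0, 1] shifts the region
color toward red and scales the noise amplitude — strongly for the
interarytenoid region (+0.20 red shift, ×3.5 noise at full inflammation)
and only weakly for the folds (+0.005, ×1.15), matching the clinical
picture in which an endotracheal tube rests on the interarytenoid mucosa
and fold color/texture changes are obscure. With the default cohort
separation (pre inflammation 0.15 ± 0.10, post 0.75 ± 0.10, truncated
normal on [0, 1]), interarytenoid features discriminate pre from post
nearly perfectly while fold features hover at AUC ≈ 0.5–0.75.

Oropharyngeal scenes render the three-beam module over two surfaces at
depths differing by `depth_offset_mm`, with a 3-px dark occluding edge at
the boundary row.

Cohort scenes are rendered at 320 × 240 px (0.1 mm/px — same field of
view), which keeps replicate studies cheap without changing any calibrated
quantity.

The phantoms deliberately do **not** emulate: lens/fisheye distortion,
specular highlights and glare, motion blur, anatomical shape variation
beyond affine layout changes, illumination gradients, or *geometric* edema
(the inflammation dial changes color/texture only, so a phantom cohort's
glottic-area percent change is ≈ 100%). Passing tests therefore demonstrate
the correctness of the measurement chain — calibration algebra, feature
definitions, index arithmetic, ROC mechanics — not robustness to clinical
image degradation, and phantom effect sizes are free parameters, not
calibrated to any clinical distribution.

## Numerical choices and degenerate inputs

* Sub-seeds for cohorts derive from `numpy.random.SeedSequence`; identical
  config + seed reproduces scenes bit-identically.
* Detection thresholds (0.25 × max signal), component-merge tolerances
  (2°, 120 px) and the minimum blob/component sizes are exposed as keyword
  arguments with those defaults.
* Fewer than two dots, or a beam count ≠ 3, raises `DetectionError` — the
  frame is treated as unusable (the operational form of a blur/glare
  exclusion rule).
* Degenerate geometry (self-intersecting or collinear polygons, coincident
  landmarks or dots, zero baselines) raises `GeometryError` /
  `CalibrationError` rather than returning NaN.
* CSV floats are serialized at 9 significant digits; a pipeline `run_log.json`
  records config hash, seed and library versions.

## Problem sizes used in the shipped studies

The test-suite and `scripts/acceptance.py` studies use 50 randomized
phantoms for scale/morphometry recovery, 50 for depth recovery, cohorts of
20 + 20 scenes (one effect cohort; 20 null replicates), 200 random images
for the GLCM oracle and 100 instances for the AUC oracle — sizes chosen so
the full suite exercises every claim in a few minutes on a laptop while
keeping the recovery statistics stable.

## Known limitations

* Annotations (region polygons, landmarks) are inputs; no automatic
  segmentation is attempted.
* The index's cohort normalization makes scores incomparable across
  cohorts; against fixed clinical reference ranges it would need re-anchoring.
* Energy and homogeneity are computed but not used by the index, matching
  its printed definition.
* The depth model's image-plane-tilt assumption (above) is untestable from
  single stills; if the physical rig tilts toward the optical axis the
  tangent relation is unchanged but the in-image appearance differs.
* Single stills only: no video handling, no lens-distortion correction,
  no multi-frame tracking.
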