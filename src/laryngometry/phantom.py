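"""Synthetic laryngeal and oropharyngeal phantom scenes.

The phantoms emulate the two endoscopic rig configurations used for
quantitative laryngoscopy:

* a **laryngeal scene** with a pair of green laser dots a known physical
  distance apart (the metric scaling reference), vocal-fold and
  interarytenoid mucosa regions whose redness and texture roughness are
  driven by an ``inflammation`` parameter in [0, 1], and a glottic-gap
  polygon of known millimetre geometry;
* an **oropharyngeal scene** with two parallel green laser lines (the
  scaling reference) plus one line tilted in the image plane, projected
  over two surfaces at different depths.  On the far surface the tilted
  line is laterally displaced by ``depth_offset_mm * tan(tilt)`` relative
  to the near surface — the triangulation relation the calibration module
  inverts.

Every scene carries a ground-truth record so downstream stages (fiducial
detection, scale recovery, morphometry, feature extraction, scoring) can be
validated without clinical data.  Generation is fully deterministic given
the config and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError
from .geometry import polygon_mask, rotate_points, shoelace_area

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PhantomScene",
    "InflammationEffect",
    "generate_laryngeal_scene",
    "generate_oropharyngeal_scene",
    "generate_cohort",
    "random_laryngeal_config",
]

# base mucosa colors (sRGB in [0, 1]); inflammation shifts these toward red
_COLOR_BACKGROUND = np.array([0.55, 0.30, 0.27])
_COLOR_FOLD = np.array([0.82, 0.60, 0.55])
_COLOR_INTERARYTENOID = np.array([0.72, 0.44, 0.40])
_COLOR_GLOTTIS = np.array([0.10, 0.04, 0.05])
_LASER_COLOR = np.array([0.08, 1.0, 0.08])  # 515 nm line laser: essentially pure green

# inflammation response: red shift (per unit inflammation) and noise gain.
# The interarytenoid region responds much more strongly than the folds
# (an endotracheal tube rests chiefly on the interarytenoid mucosa); the
# fold response is kept comparable to region-averaging noise so fold
# features discriminate only weakly, as seen clinically.
_FOLD_RED_SHIFT = np.array([0.005, -0.002, -0.001])
_IA_RED_SHIFT = np.array([0.20, -0.06, -0.02])
_FOLD_NOISE_GAIN = 0.15
_IA_NOISE_GAIN = 2.5


@dataclass
class PhantomConfig:
    """Parameters of a synthetic scene.

    Geometry is laid out in millimetres about the scene centre and converted
    to pixels with ``mm_per_px_true``.  ``inflammation`` in [0, 1] drives the
    mucosal red shift and texture-noise amplitude.
    """

    image_width: int = 640
    image_height: int = 480
    mm_per_px_true: float = 0.05
    dot_separation_mm: float = 1.0
    line_tilt_deg: float = 8.5
    line_separation_mm: float = 10.0
    glottis_polygon_mm: np.ndarray | None = None
    glottis_length_mm: float = 12.0
    glottis_halfwidth_mm: float = 1.5
    fold_width_mm: float = 3.0
    interarytenoid_mm: tuple[float, float] = (9.0, 4.0)
    inflammation: float = 0.0
    depth_offset_mm: float = 0.0
    tilted_base_offset_mm: float = 3.0
    noise_sd: float = 0.06
    noise_smooth_px: float = 1.2
    layout_angle_deg: float = 0.0
    centre_offset_mm: tuple[float, float] = (0.0, 0.0)
    dot_centre_frac: tuple[float, float] = (0.16, 0.13)
    seed: int = 0

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.mm_per_px_true <= 0:
            raise ConfigError("mm_per_px_true must be positive")
        if not (0.0 <= self.inflammation <= 1.0):
            raise ConfigError("inflammation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not (0.0 < self.line_tilt_deg < 90.0):
            raise ConfigError("line_tilt_deg must lie in (0, 90) degrees")
        if self.depth_offset_mm < 0:
            raise ConfigError("depth_offset_mm must be non-negative")
        if self.glottis_polygon_mm is not None:
            pts = np.asarray(self.glottis_polygon_mm, float)
            if len(pts) < 3 or shoelace_area(pts) <= 0:
                raise ConfigError("glottis polygon needs >= 3 non-collinear vertices")


@dataclass
class PhantomTruth:
    """Ground truth for one scene (pixel coordinates unless suffixed _mm)."""

    mm_per_px: float
    dot_centers: np.ndarray | None = None
    regions: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    morphometry_mm: dict = field(default_factory=dict)
    depth_offset_mm: float | None = None
    reference_line_x: tuple[float, float] | None = None
    boundary_row: int | None = None
    near_offset_mm: float | None = None
    far_offset_mm: float | None = None
    tilt_deg: float | None = None


@dataclass
class PhantomScene:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    truth: PhantomTruth
    config: PhantomConfig


@dataclass
class InflammationEffect:
    """Class-conditional inflammation distributions for a pre/post cohort.

    Draws are truncated normals on [0, 1].  ``zero()`` gives identical
    pre/post distributions (a null cohort); ``large()`` gives the default
    well-separated condition.
    """

    pre_mean: float = 0.15
    post_mean: float = 0.75
    sd: float = 0.10

    @classmethod
    def large(cls) -> "InflammationEffect":
        return cls()

    @classmethod
    def zero(cls, mean: float = 0.45, sd: float = 0.10) -> "InflammationEffect":
        return cls(pre_mean=mean, post_mean=mean, sd=sd)


def _default_glottis_polygon(length_mm: float, halfwidth_mm: float, n: int = 24) -> np.ndarray:
    """Lens-shaped glottic gap: pointed anteriorly and posteriorly."""
    t = np.linspace(0.0, 1.0, n // 2)
    y = -length_mm / 2 + length_mm * t
    x = halfwidth_mm * np.sin(np.pi * t)
    right = np.column_stack([x, y])
    left = np.column_stack([-x[::-1], y[::-1]])
    pts = np.vstack([right[:-1], left[:-1]])
    return pts


def _check_in_raster(pts: np.ndarray, w: int, h: int, what: str) -> None:
    if pts[:, 0].min() < 1 or pts[:, 0].max() > w - 2 or pts[:, 1].min() < 1 or pts[:, 1].max() > h - 2:
        raise GeometryError(f"{what} falls outside the raster")


def _smoothed_noise(rng: np.random.Generator, h: int, w: int, smooth_px: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian field (mucosal micro-texture)."""
    n = rng.standard_normal((h, w))
    if smooth_px > 0:
        n = ndimage.gaussian_filter(n, smooth_px)
        sd = n.std()
        if sd > 0:
            n = n / sd
    return n


def _render_dot(image: np.ndarray, center: tuple[float, float], sigma: float = 2.0) -> None:
    """Blend a Gaussian laser-dot profile into the raster at a sub-pixel center."""
    h, w = image.shape[:2]
    cx, cy = center
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    wgt = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    patch = image[y0:y1, x0:x1]
    image[y0:y1, x0:x1] = patch * (1 - wgt[..., None]) + _LASER_COLOR * wgt[..., None]


def _render_line_column(image, rows, x_of_row, sigma: float = 1.2) -> None:
    """Blend a near-vertical laser line; ``x_of_row`` maps row -> center column."""
    h, w = image.shape[:2]
    half = int(np.ceil(4 * sigma))
    for y in rows:
        xc = x_of_row(y)
        x0, x1 = max(int(xc) - half, 0), min(int(xc) + half + 1, w)
        if x0 >= x1:
            continue
        xs = np.arange(x0, x1)
        wgt = np.exp(-((xs - xc) ** 2) / (2 * sigma**2))
        image[y, x0:x1] = image[y, x0:x1] * (1 - wgt[:, None]) + _LASER_COLOR * wgt[:, None]


def generate_laryngeal_scene(config: PhantomConfig) -> PhantomScene:
    """Render a laryngeal phantom with dot fiducials and ground truth."""
    config.validate()
    w, h = config.image_width, config.image_height
    s = config.mm_per_px_true
    rng = np.random.default_rng(config.seed)

    # --- geometry in mm about the scene centre -------------------------------
    if config.glottis_polygon_mm is not None:
        glottis_mm = np.asarray(config.glottis_polygon_mm, float)
        length = glottis_mm[:, 1].max() - glottis_mm[:, 1].min()
        halfwidth = (glottis_mm[:, 0].max() - glottis_mm[:, 0].min()) / 2.0
    else:
        length, halfwidth = config.glottis_length_mm, config.glottis_halfwidth_mm
        glottis_mm = _default_glottis_polygon(length, halfwidth)

    fw = config.fold_width_mm
    fold_left_mm = np.array(
        [[-halfwidth - fw, -length / 2], [-halfwidth, -length / 2],
         [-halfwidth, length / 2], [-halfwidth - fw, length / 2]]
    )
    fold_right_mm = fold_left_mm * np.array([-1.0, 1.0])
    ia_w, ia_h = config.interarytenoid_mm
    gap = 0.5  # mm between posterior glottis tip and the interarytenoid band
    ia_mm = np.array(
        [[-ia_w / 2, length / 2 + gap], [ia_w / 2, length / 2 + gap],
         [ia_w / 2, length / 2 + gap + ia_h], [-ia_w / 2, length / 2 + gap + ia_h]]
    )
    landmarks_mm = {
        "anterior_commissure": np.array([0.0, -length / 2]),
        "left_process": np.array([-halfwidth, length / 2]),
        "right_process": np.array([halfwidth, length / 2]),
    }

    centre_px = np.array([w / 2, h / 2]) + np.asarray(config.centre_offset_mm) / s

    def to_px(pts_mm):
        pts = rotate_points(np.atleast_2d(pts_mm), config.layout_angle_deg)
        return centre_px + pts / s

    regions_px = {
        "glottis": to_px(glottis_mm),
        "vocal_fold_left": to_px(fold_left_mm),
        "vocal_fold_right": to_px(fold_right_mm),
        "interarytenoid": to_px(ia_mm),
    }
    landmarks_px = {k: to_px(v)[0] for k, v in landmarks_mm.items()}
    for name, pts in regions_px.items():
        _check_in_raster(pts, w, h, f"{name} polygon")

    # --- raster --------------------------------------------------------------
    image = np.empty((h, w, 3), float)
    image[:] = _COLOR_BACKGROUND
    infl = config.inflammation
    fold_color = np.clip(_COLOR_FOLD + infl * _FOLD_RED_SHIFT, 0, 1)
    ia_color = np.clip(_COLOR_INTERARYTENOID + infl * _IA_RED_SHIFT, 0, 1)

    masks = {name: polygon_mask((h, w), pts) for name, pts in regions_px.items()}
    image[masks["interarytenoid"]] = ia_color
    image[masks["vocal_fold_left"]] = fold_color
    image[masks["vocal_fold_right"]] = fold_color

    # texture: one shared smoothed noise field, region-dependent amplitude
    noise = _smoothed_noise(rng, h, w, config.noise_smooth_px)
    amp = np.full((h, w), config.noise_sd)
    amp[masks["vocal_fold_left"] | masks["vocal_fold_right"]] = config.noise_sd * (1 + _FOLD_NOISE_GAIN * infl)
    amp[masks["interarytenoid"]] = config.noise_sd * (1 + _IA_NOISE_GAIN * infl)
    channel_gain = np.array([1.0, 0.8, 0.7])
    image = np.clip(image + (amp * noise)[..., None] * channel_gain, 0, 1)

    image[masks["glottis"]] = _COLOR_GLOTTIS  # dark airway gap, featureless

    # --- laser dot fiducials -------------------------------------------------
    base = np.array([w * config.dot_centre_frac[0], h * config.dot_centre_frac[1]])
    base = base + rng.uniform(-0.5, 0.5, size=2)  # exercise sub-pixel positions
    sep_px = config.dot_separation_mm / s
    dots = np.array([base, base + [sep_px, 0.0]])
    if dots[:, 0].max() > w - 10 or dots[:, 1].max() > h - 10:
        raise GeometryError("laser dots fall outside the raster")
    for c in dots:
        _render_dot(image, (c[0], c[1]))

    truth = PhantomTruth(
        mm_per_px=s,
        dot_centers=dots,
        regions={k: v.copy() for k, v in regions_px.items()},
        landmarks=landmarks_px,
        morphometry_mm={
            "vocal_length_mm": length,
            "vocal_width_mm": fw,
            "vocal_area_mm2": length * fw,
            "glottic_area_mm2": shoelace_area(glottis_mm),
            "vocal_angle_deg": float(np.rad2deg(2 * np.arctan2(halfwidth, length))),
        },
    )
    return PhantomScene(image=image, truth=truth, config=dataclasses.replace(config))


def generate_oropharyngeal_scene(config: PhantomConfig) -> PhantomScene:
    """Render an oropharyngeal phantom: two parallel reference lines plus a
    tilted line over two surfaces at depths differing by ``depth_offset_mm``.

    A 3-px dark band at the surface boundary models the occluding edge
    between the near and far surfaces, so each laser beam forms one connected
    blob per surface.  Ground-truth lateral offsets of the tilted line from
    the left reference line are defined at the boundary row.
    """
    config.validate()
    w, h = config.image_width, config.image_height
    s = config.mm_per_px_true
    rng = np.random.default_rng(config.seed)

    boundary = h // 2
    image = np.empty((h, w, 3), float)
    image[:] = np.array([0.42, 0.22, 0.21])  # near surface (soft palate)
    image[boundary:] = np.array([0.33, 0.16, 0.17])  # far surface (posterior wall)
    noise = _smoothed_noise(rng, h, w, config.noise_smooth_px)
    image = np.clip(image + (config.noise_sd * 0.5) * noise[..., None], 0, 1)
    image[boundary - 1 : boundary + 2] = 0.05  # occluding shelf edge

    x_ref1 = w * 0.22 + rng.uniform(-0.5, 0.5)
    x_ref2 = x_ref1 + config.line_separation_mm / s
    slope = np.tan(np.deg2rad(config.line_tilt_deg))  # px of x per px of y
    x_anchor = x_ref1 + config.tilted_base_offset_mm / s  # tilted line at boundary, near surface
    jump_px = config.depth_offset_mm * slope / s

    far_x_max = x_anchor + jump_px + (h - boundary) * slope
    if x_ref2 > w - 8 or far_x_max > w - 8:
        raise GeometryError("laser lines fall outside the raster")

    rows_near = range(0, boundary - 1)
    rows_far = range(boundary + 2, h)
    for x_ref in (x_ref1, x_ref2):
        _render_line_column(image, rows_near, lambda y, xr=x_ref: xr)
        _render_line_column(image, rows_far, lambda y, xr=x_ref: xr)
    _render_line_column(image, rows_near, lambda y: x_anchor + (y - boundary) * slope)
    _render_line_column(image, rows_far, lambda y: x_anchor + jump_px + (y - boundary) * slope)

    near_offset_mm = (x_anchor - x_ref1) * s
    far_offset_mm = near_offset_mm + config.depth_offset_mm * np.tan(np.deg2rad(config.line_tilt_deg))
    truth = PhantomTruth(
        mm_per_px=s,
        depth_offset_mm=config.depth_offset_mm,
        reference_line_x=(x_ref1, x_ref2),
        boundary_row=boundary,
        near_offset_mm=near_offset_mm,
        far_offset_mm=far_offset_mm,
        tilt_deg=config.line_tilt_deg,
    )
    return PhantomScene(image=image, truth=truth, config=dataclasses.replace(config))


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Truncated-normal draws on [0, 1] by rejection (sd is the parent SD)."""
    if sd == 0:
        return np.full(n, np.clip(mean, 0, 1))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw >= 0) & (draw <= 1)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


# cohort scenes are rendered at half linear resolution (same field of view) to
# keep large replicate studies cheap; geometry and features scale with mm/px.
_COHORT_BASE = dict(image_width=320, image_height=240, mm_per_px_true=0.1)


def generate_cohort(
    n_per_class: int,
    effect: InflammationEffect,
    seed: int,
    base_config: PhantomConfig | None = None,
) -> list[tuple[PhantomScene, str]]:
    """Generate a pre/post laryngeal cohort with class-specific inflammation.

    Returns ``2 * n_per_class`` scenes labelled ``"pre"`` / ``"post"``; all
    per-scene seeds derive from the master ``seed``.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    base = base_config if base_config is not None else PhantomConfig(**_COHORT_BASE)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    levels = np.concatenate(
        [
            _truncnorm_draw(rng, effect.pre_mean, effect.sd, n_per_class),
            _truncnorm_draw(rng, effect.post_mean, effect.sd, n_per_class),
        ]
    )
    labels = ["pre"] * n_per_class + ["post"] * n_per_class
    scene_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    out = []
    for level, label, sseed in zip(levels, labels, scene_seeds):
        cfg = dataclasses.replace(base, inflammation=float(level), seed=int(sseed))
        out.append((generate_laryngeal_scene(cfg), label))
    return out


def random_laryngeal_config(rng: np.random.Generator, mm_per_px: float | None = None) -> PhantomConfig:
    """Randomized laryngeal geometry scaled to fit the field of view.

    Used for recovery studies: scale in [0.02, 0.1] mm/px, fold width/length,
    layout rotation and inflammation all vary; everything stays inside the
    raster by construction.
    """
    if mm_per_px is None:
        mm_per_px = float(rng.uniform(0.02, 0.1))
    w, hgt = 640, 480
    fov_h = hgt * mm_per_px
    length = float(rng.uniform(0.30, 0.45)) * fov_h
    halfwidth = length * float(rng.uniform(0.07, 0.12))
    fold_w = length * float(rng.uniform(0.14, 0.25))
    ia = (length * 0.7, length * 0.3)
    return PhantomConfig(
        image_width=w,
        image_height=hgt,
        mm_per_px_true=mm_per_px,
        glottis_length_mm=length,
        glottis_halfwidth_mm=halfwidth,
        fold_width_mm=fold_w,
        interarytenoid_mm=ia,
        layout_angle_deg=float(rng.uniform(-20, 20)),
        inflammation=float(rng.uniform(0, 1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
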