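"""Per-region color (RGB means, CIELab) and GLCM texture features.

"Hue" features follow the channel-wise convention used in endoscopic
inflammation work: the mean R, G and B intensity of a region, analysed per
channel, not the HSV hue angle.  CIELab coordinates are computed from the
region's mean sRGB color through the standard sRGB → XYZ (D65) → CIELab
mapping.

Texture is summarized by the gray-level co-occurrence matrix (GLCM): the
normalized joint histogram of quantized intensity pairs at fixed pixel
offsets, computed per color channel.  Four scalar features are derived:

    energy      = Σ p(i,j)²                      (uniformity of the histogram)
    contrast    = Σ (i−j)² p(i,j)                (local intensity variation)
    homogeneity = Σ p(i,j) / (1 + (i−j)²)        (closeness to the diagonal)
    correlation = Σ (i−μᵢ)(j−μⱼ) p(i,j) / σᵢσⱼ   (:= 1 when σᵢσⱼ = 0)

Features are computed per offset and averaged over the offset set.
Intensities are quantized into ``levels`` equal-width bins over the fixed
range [0, 1], so texture amplitude differences between images are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage import color as skcolor

from .errors import ConfigError, GeometryError, RegionError
from .geometry import polygon_mask, validate_simple_polygon

__all__ = [
    "REGION_LABELS",
    "LANDMARK_NAMES",
    "RegionAnnotation",
    "ColorProfile",
    "GlcmFeatures",
    "TextureProfile",
    "GlcmParams",
    "rgb_to_cielab",
    "glcm",
    "texture_features",
    "region_profiles",
]

REGION_LABELS = frozenset(
    {"vocal_fold_left", "vocal_fold_right", "interarytenoid", "glottis", "oropharyngeal_inlet"}
)
LANDMARK_NAMES = frozenset({"anterior_commissure", "left_process", "right_process"})
CHANNELS = ("R", "G", "B")


@dataclass
class RegionAnnotation:
    """A labelled polygon (pixel coordinates) with optional landmarks."""

    label: str
    polygon: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in REGION_LABELS:
            raise GeometryError(f"unknown region label {self.label!r}; expected one of {sorted(REGION_LABELS)}")
        validate_simple_polygon(self.polygon)
        self.polygon = np.asarray(self.polygon, float)
        self.landmarks = {k: np.asarray(v, float) for k, v in self.landmarks.items()}


@dataclass
class ColorProfile:
    mean_R: float
    mean_G: float
    mean_B: float
    L_star: float
    a_star: float
    b_star: float
    pixel_count: int = 0


class GlcmFeatures(NamedTuple):
    energy: float
    contrast: float
    correlation: float
    homogeneity: float


@dataclass
class TextureProfile:
    """GLCM features per color channel (keys "R", "G", "B")."""

    channels: dict[str, GlcmFeatures]
    pixel_count: int = 0


@dataclass
class GlcmParams:
    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ConfigError("GLCM levels must be >= 2")
        if not self.offsets:
            raise ConfigError("GLCM offsets must be non-empty")
        for off in self.offsets:
            if tuple(off) == (0, 0):
                raise ConfigError("GLCM offset (0, 0) is not allowed")


def rgb_to_cielab(rgb) -> tuple[float, float, float]:
    """sRGB (components in [0, 1]) to CIELab, two-stage: sRGB → XYZ → Lab.

    The XYZ stage is skimage's sRGB (D65) linearization; the Lab stage
    normalizes by the exact sRGB matrix white (XYZ of RGB = (1,1,1)) so that
    white maps to (100, 0, 0) and every gray sits exactly on the neutral
    axis a* = b* = 0.  Accepts a single RGB triple or an (..., 3) array.
    """
    arr = np.asarray(rgb, float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB with 3 components on the last axis")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("RGB components must lie in [0, 1]")
    xyz = skcolor.rgb2xyz(arr.reshape(-1, 1, 3))
    white = skcolor.rgb2xyz(np.ones((1, 1, 3)))[0, 0]
    t = xyz.reshape(-1, 3) / white
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[:, 1] - 16.0
    a = 500.0 * (f[:, 0] - f[:, 1])
    b = 200.0 * (f[:, 1] - f[:, 2])
    lab = np.stack([L, a, b], axis=-1).reshape(arr.shape)
    if lab.ndim == 1:
        return float(lab[0]), float(lab[1]), float(lab[2])
    return lab


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 1] intensities into ``levels`` bins."""
    v = np.asarray(values, float)
    q = np.floor(v * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm(image_region: np.ndarray, params: GlcmParams | None = None, mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized co-occurrence matrices of a single-channel raster.

    Returns an array of shape ``(levels, levels, n_offsets)``; each offset's
    matrix is symmetrized if requested and normalized to sum 1.  When a
    boolean ``mask`` is given, only pixel pairs with both ends inside the
    mask are counted.  An offset ``(dy, dx)`` pairs pixel (y, x) with pixel
    (y + dy, x + dx).
    """
    params = params or GlcmParams()
    img = np.asarray(image_region, float)
    if img.ndim != 2:
        raise RegionError("expected a single-channel (2-D) raster")
    if mask is None:
        mask = np.ones(img.shape, bool)
    if mask.sum() < 2:
        raise RegionError("region must contain at least 2 pixels")
    q = quantize(img, params.levels)
    h, w = img.shape
    L = params.levels
    out = np.zeros((L, L, len(params.offsets)))
    for k, (dy, dx) in enumerate(params.offsets):
        y0a, y1a = max(0, -dy), min(h, h - dy)
        x0a, x1a = max(0, -dx), min(w, w - dx)
        if y0a >= y1a or x0a >= x1a:
            continue
        a = q[y0a:y1a, x0a:x1a]
        b = q[y0a + dy : y1a + dy, x0a + dx : x1a + dx]
        valid = mask[y0a:y1a, x0a:x1a] & mask[y0a + dy : y1a + dy, x0a + dx : x1a + dx]
        if not valid.any():
            continue
        pairs = a[valid] * L + b[valid]
        m = np.bincount(pairs, minlength=L * L).reshape(L, L).astype(float)
        if params.symmetric:
            m = m + m.T
        total = m.sum()
        if total > 0:
            m /= total
        out[:, :, k] = m
    if out.sum() == 0:
        raise RegionError("region yields no valid pixel pairs for any offset")
    return out


def _features_single(m: np.ndarray) -> GlcmFeatures:
    L = m.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    energy = float((m**2).sum())
    contrast = float(((i - j) ** 2 * m).sum())
    homogeneity = float((m / (1.0 + (i - j) ** 2)).sum())
    pi = m.sum(axis=1)
    pj = m.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        corr = 1.0  # perfectly homogeneous region is perfectly predictable
    else:
        corr = float((((i - mu_i) * (j - mu_j) * m).sum()) / denom)
    return GlcmFeatures(energy=energy, contrast=contrast, correlation=corr, homogeneity=homogeneity)


def texture_features(matrix: np.ndarray) -> GlcmFeatures:
    """Energy, contrast, correlation, homogeneity of normalized GLCM(s).

    Accepts one matrix ``(L, L)`` or a stack ``(L, L, K)``; features are
    computed per offset and averaged.
    """
    m = np.asarray(matrix, float)
    if m.ndim == 2:
        m = m[:, :, None]
    if m.ndim != 3 or m.shape[0] != m.shape[1]:
        raise ValueError("expected an (L, L) or (L, L, K) co-occurrence matrix")
    if np.any(m < 0):
        raise ValueError("co-occurrence matrix entries must be non-negative")
    feats = []
    for k in range(m.shape[2]):
        mk = m[:, :, k]
        if mk.sum() == 0:
            continue  # offset had no valid pixel pairs (e.g. 1-px-wide region)
        if abs(mk.sum() - 1.0) > 1e-8:
            raise ValueError("each co-occurrence matrix must be normalized to sum 1")
        feats.append(_features_single(mk))
    if not feats:
        raise ValueError("no offset produced a non-empty co-occurrence matrix")
    arr = np.array(feats)
    return GlcmFeatures(*[float(v) for v in arr.mean(axis=0)])


def region_profiles(
    image: np.ndarray,
    annotation: RegionAnnotation,
    params: GlcmParams | None = None,
    per_pixel_lab: bool = False,
    grayscale: bool = False,
) -> tuple[ColorProfile, TextureProfile]:
    """Color and texture profile of one annotated region.

    Pixels inside the polygon (even-odd rule on pixel centers) contribute to
    the channel means; CIELab is computed from the mean RGB (or as the mean
    of per-pixel Lab when ``per_pixel_lab``).  GLCM features are computed per
    channel, or on the luminance image when ``grayscale``.
    """
    params = params or GlcmParams()
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise RegionError("expected an RGB raster")
    mask = polygon_mask(img.shape[:2], annotation.polygon)
    npix = int(mask.sum())
    if npix == 0:
        raise RegionError(f"region {annotation.label!r} covers no pixel centers inside the raster")

    # crop to the mask's bounding box: co-occurrence only needs local context
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop = img[y0:y1, x0:x1]
    cmask = mask[y0:y1, x0:x1]

    means = [float(crop[..., c][cmask].mean()) for c in range(3)]
    if per_pixel_lab:
        lab = rgb_to_cielab(np.clip(crop[cmask], 0, 1))
        L, a, b = (float(v) for v in lab.mean(axis=0))
    else:
        L, a, b = rgb_to_cielab(np.clip(means, 0, 1))
    color = ColorProfile(*means, L_star=L, a_star=a, b_star=b, pixel_count=npix)

    if grayscale:
        gray = skcolor.rgb2gray(crop)
        feats = texture_features(glcm(gray, params, cmask))
        texture = TextureProfile(channels={"gray": feats}, pixel_count=npix)
    else:
        channels = {
            name: texture_features(glcm(crop[..., c], params, cmask))
            for c, name in enumerate(CHANNELS)
        }
        texture = TextureProfile(channels=channels, pixel_count=npix)
    return color, texture
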