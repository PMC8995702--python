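"""Laser-fiducial detection and pixel-to-millimetre calibration.

Two rig geometries are supported:

* **dot pair** — two parallel laser beams a known physical distance apart
  (1 mm by default) project as two bright green dots; the pixel distance
  between their sub-pixel centroids gives the metric scale,
  ``mm_per_px = separation_mm / pixel_distance``;
* **line triple** — two parallel laser lines (scaling reference) plus one
  beam tilted by a known angle θ.  A surface farther from the endoscope by
  ``d`` shifts the tilted line laterally by ``d * tan(θ)``, so depth follows
  from the change in the tilted line's offset between two surfaces:
  ``d = (far_offset_mm − near_offset_mm) / tan(θ)``.

The dot separation is treated as depth-independent over the working range,
and the tilted beam is modelled as tilted in the image plane with its
surface intersection displaced laterally in proportion to depth.  Both are
stated modelling conventions of this package (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .errors import CalibrationError, ConfigError, DetectionError

__all__ = [
    "CalibrationScale",
    "FittedLine",
    "LineSet",
    "DepthMeasurement",
    "laser_signal",
    "detect_laser_dots",
    "scale_from_dots",
    "detect_laser_lines",
    "scale_from_lines",
    "measure_line_offsets",
    "depth_from_line_offset",
]


@dataclass
class CalibrationScale:
    """Metric scale of one image: millimetres per pixel plus provenance."""

    mm_per_px: float
    dot_centers: np.ndarray | None = None
    quality: float = 1.0

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise CalibrationError("mm_per_px must be positive")


@dataclass
class FittedLine:
    """A line in pixel space: a point on it plus a unit direction."""

    point: np.ndarray
    direction: np.ndarray
    n_pixels: int = 0

    def angle_deg(self) -> float:
        """Orientation in [0, 180) degrees, measured from the +x axis."""
        return float(np.rad2deg(np.arctan2(self.direction[1], self.direction[0])) % 180.0)

    def x_at_row(self, y: float) -> float:
        dx, dy = self.direction
        if abs(dy) < 1e-12:
            raise CalibrationError("line is horizontal; cannot evaluate x at a row")
        t = (y - self.point[1]) / dy
        return float(self.point[0] + t * dx)

    def signed_distance(self, pt) -> float:
        """Signed perpendicular distance from ``pt`` to this line."""
        normal = np.array([-self.direction[1], self.direction[0]])
        return float(np.dot(np.asarray(pt, float) - self.point, normal))


@dataclass
class LineSet:
    reference_lines: tuple[FittedLine, FittedLine]
    tilted_line: FittedLine
    tilt_deg: float
    tilted_segments: list[FittedLine] = field(default_factory=list)


@dataclass
class DepthMeasurement:
    near_offset_mm: float
    far_offset_mm: float
    depth_mm: float


def laser_signal(image: np.ndarray) -> np.ndarray:
    """Green-dominance map highlighting the 515 nm laser against mucosa.

    Mucosa is red-dominant, so ``G − (R + B)/2`` is strongly positive only on
    laser pixels.  A 3×3 median filter suppresses isolated noise.
    """
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DetectionError("expected an RGB raster")
    s = img[..., 1] - 0.5 * (img[..., 0] + img[..., 2])
    return ndimage.median_filter(np.clip(s, 0, None), size=3)


def _refine_gaussian_center(s: np.ndarray, x0: float, y0: float, half: int = 8) -> np.ndarray:
    """Least-squares 2-D Gaussian refinement of a blob center on a local patch."""
    h, w = s.shape
    xa, xb = max(int(x0) - half, 0), min(int(x0) + half + 1, w)
    ya, yb = max(int(y0) - half, 0), min(int(y0) + half + 1, h)
    patch = s[ya:yb, xa:xb]
    xs, ys = np.meshgrid(np.arange(xa, xb), np.arange(ya, yb))

    def resid(p):
        amp, cx, cy, sig, off = p
        model = amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sig**2)) + off
        return (model - patch).ravel()

    p0 = [float(patch.max()), x0, y0, 2.0, float(np.median(patch))]
    try:
        res = optimize.least_squares(resid, p0, max_nfev=200)
        cx, cy = res.x[1], res.x[2]
        if abs(cx - x0) < half and abs(cy - y0) < half:
            return np.array([cx, cy])
    except Exception:
        pass
    return np.array([x0, y0])


def detect_laser_dots(
    image: np.ndarray,
    min_blob_px: int = 4,
    threshold_frac: float = 0.25,
    refine: bool = True,
) -> np.ndarray:
    """Locate the two laser-dot fiducials at sub-pixel precision.

    Thresholds the green-dominance map, labels connected components, ranks
    blobs by integrated intensity and returns the centroids of the two
    brightest, ordered by x then y.  Raises :class:`DetectionError` when
    fewer than two blobs are found (unusable frame).
    """
    s = laser_signal(image)
    smax = float(s.max())
    if smax < 0.2:
        raise DetectionError("no laser-bright pixels found")
    thr = threshold_frac * smax
    labels, n = ndimage.label(s > thr)
    if n < 2:
        raise DetectionError(f"found {n} laser blob(s); need 2")
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(s), labels, idx)
    mass = ndimage.sum_labels(s, labels, idx)
    keep = idx[sizes >= min_blob_px]
    if len(keep) < 2:
        raise DetectionError("fewer than 2 laser blobs above the minimum size")
    order = keep[np.argsort(-mass[keep - 1])][:2]
    centers = []
    for lab in order:
        ys, xs = np.nonzero(labels == lab)
        wts = s[ys, xs]
        cx, cy = float(np.average(xs, weights=wts)), float(np.average(ys, weights=wts))
        if refine:
            cx, cy = _refine_gaussian_center(s, cx, cy)
        centers.append([cx, cy])
    centers = np.array(sorted(centers, key=lambda c: (c[0], c[1])))
    return centers


def scale_from_dots(dots: np.ndarray, separation_mm: float = 1.0) -> CalibrationScale:
    """Metric scale from the dot-pair fiducial: mm_per_px = separation / distance."""
    dots = np.asarray(dots, float)
    if separation_mm <= 0:
        raise CalibrationError("separation_mm must be positive")
    dist = float(np.hypot(*(dots[1] - dots[0])))
    if dist < 1e-9:
        raise CalibrationError("dot centers coincide")
    return CalibrationScale(mm_per_px=separation_mm / dist, dot_centers=dots)


def _fit_line_tls(xs: np.ndarray, ys: np.ndarray, weights: np.ndarray | None = None) -> FittedLine:
    """Total-least-squares line through weighted pixel coordinates."""
    pts = np.column_stack([xs, ys]).astype(float)
    if weights is None:
        weights = np.ones(len(pts))
    mean = np.average(pts, axis=0, weights=weights)
    d = (pts - mean) * np.sqrt(weights)[:, None]
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    direction = vt[0]
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction
    return FittedLine(point=mean, direction=direction, n_pixels=len(pts))


def _angle_between(a: FittedLine, b: FittedLine) -> float:
    """Acute angle between two lines in degrees."""
    diff = abs(a.angle_deg() - b.angle_deg()) % 180.0
    return min(diff, 180.0 - diff)


def detect_laser_lines(
    image: np.ndarray,
    tilt_deg: float = 8.5,
    threshold_frac: float = 0.25,
    min_comp_px: int = 30,
    angle_merge_deg: float = 2.0,
    perp_merge_px: float = 120.0,
) -> LineSet:
    """Detect the three-beam line fiducial (two parallel + one tilted).

    Connected laser components are fitted with total-least-squares lines and
    merged into *beams* when near-parallel and laterally close (a beam may be
    split into one component per surface by the occluding depth edge).  The
    beam pair with minimal mutual angle becomes the reference pair; the
    remaining beam is the tilted one.  Raises :class:`DetectionError` unless
    exactly three beams are found.
    """
    if not (0.0 < tilt_deg < 90.0):
        raise ConfigError("tilt_deg must lie in (0, 90) degrees")
    s = laser_signal(image)
    smax = float(s.max())
    if smax < 0.2:
        raise DetectionError("no laser-bright pixels found")
    labels, n = ndimage.label(s > threshold_frac * smax)
    comps = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(xs) < min_comp_px:
            continue
        comps.append(_fit_line_tls(xs, ys, s[ys, xs]))
    if len(comps) < 3:
        raise DetectionError(f"found {len(comps)} laser line component(s); need >= 3")

    # union-find merge of near-parallel, laterally close components into beams
    parent = list(range(len(comps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if _angle_between(comps[i], comps[j]) <= angle_merge_deg:
                if abs(comps[i].signed_distance(comps[j].point)) <= perp_merge_px:
                    parent[find(i)] = find(j)

    beams: dict[int, list[FittedLine]] = {}
    for i, c in enumerate(comps):
        beams.setdefault(find(i), []).append(c)
    beam_list = list(beams.values())
    if len(beam_list) != 3:
        raise DetectionError(f"found {len(beam_list)} laser beams; need exactly 3")

    # representative line per beam = fit of its largest component
    reps = [max(b, key=lambda c: c.n_pixels) for b in beam_list]
    pairs = [(0, 1), (0, 2), (1, 2)]
    i, j = min(pairs, key=lambda p: _angle_between(reps[p[0]], reps[p[1]]))
    k = ({0, 1, 2} - {i, j}).pop()
    refs = sorted([reps[i], reps[j]], key=lambda line: line.point[0])
    segments = sorted(beam_list[k], key=lambda c: c.point[1])
    tilted = max(segments, key=lambda c: c.n_pixels)
    return LineSet(
        reference_lines=(refs[0], refs[1]),
        tilted_line=tilted,
        tilt_deg=tilt_deg,
        tilted_segments=segments,
    )


def scale_from_lines(lines: LineSet, separation_mm: float) -> CalibrationScale:
    """Metric scale from the parallel reference-line pair."""
    if separation_mm <= 0:
        raise CalibrationError("separation_mm must be positive")
    ref1, ref2 = lines.reference_lines
    dist = abs(ref1.signed_distance(ref2.point))
    if dist < 1e-9:
        raise CalibrationError("reference lines coincide")
    return CalibrationScale(mm_per_px=separation_mm / dist)


def measure_line_offsets(
    lines: LineSet, boundary_row: float, scale: CalibrationScale
) -> tuple[float, float]:
    """Lateral offsets (mm) of the tilted beam from the left reference line.

    Both per-surface segments of the tilted beam are extrapolated to the
    surface-boundary row and their perpendicular distance to the left
    reference line is converted to millimetres.  Evaluating both at the same
    row isolates the depth-induced lateral jump from the beam's in-plane
    tilt.  With a single segment (flat scene) near and far offsets coincide.
    """
    ref = lines.reference_lines[0]
    segs = lines.tilted_segments if lines.tilted_segments else [lines.tilted_line]
    near_seg, far_seg = segs[0], segs[-1]
    near_pt = np.array([near_seg.x_at_row(boundary_row), boundary_row])
    far_pt = np.array([far_seg.x_at_row(boundary_row), boundary_row])
    near = abs(ref.signed_distance(near_pt)) * scale.mm_per_px
    far = abs(ref.signed_distance(far_pt)) * scale.mm_per_px
    return near, far


def depth_from_line_offset(
    lines: LineSet, near_offset_mm: float, far_offset_mm: float
) -> DepthMeasurement:
    """Invert the triangulation relation: depth = Δoffset / tan(θ)."""
    if not (0.0 < lines.tilt_deg < 90.0):
        raise ConfigError("tilt_deg must lie in (0, 90) degrees")
    if not (np.isfinite(near_offset_mm) and np.isfinite(far_offset_mm)):
        raise ValueError("offsets must be finite")
    depth = (far_offset_mm - near_offset_mm) / np.tan(np.deg2rad(lines.tilt_deg))
    return DepthMeasurement(
        near_offset_mm=float(near_offset_mm),
        far_offset_mm=float(far_offset_mm),
        depth_mm=float(depth),
    )
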