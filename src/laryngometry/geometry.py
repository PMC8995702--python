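"""Polygon and raster geometry helpers shared across modules.

Pixel convention: coordinates are 0-based, origin at the top-left corner,
x increasing rightward (columns), y increasing downward (rows).  A pixel
(x, y) is identified with the point (x, y), i.e. integer coordinates name
pixel centers.  Polygons are sequences of (x, y) vertices, implicitly closed.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path
from shapely.geometry import LineString, Polygon

from .errors import GeometryError

__all__ = [
    "as_polygon_array",
    "validate_simple_polygon",
    "shoelace_area",
    "polygon_centroid",
    "polygon_mask",
    "polygon_principal_axis",
    "rotate_points",
]


def as_polygon_array(polygon) -> np.ndarray:
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError(f"polygon must be an (N, 2) point list, got shape {pts.shape}")
    return pts


def validate_simple_polygon(polygon) -> Polygon:
    """Return a shapely Polygon, raising GeometryError for degenerate input.

    A polygon must have at least three vertices, non-zero area and no
    self-intersections (it must be *simple* in the planar sense).
    """
    pts = as_polygon_array(polygon)
    if len(pts) < 3:
        raise GeometryError(f"polygon needs >= 3 vertices, got {len(pts)}")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("polygon is self-intersecting or otherwise invalid")
    if poly.area <= 0:
        raise GeometryError("polygon has zero area (collinear vertices)")
    return poly


def shoelace_area(polygon) -> float:
    """Unsigned polygon area by the shoelace formula (vertex-exact)."""
    pts = as_polygon_array(polygon)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_centroid(polygon) -> np.ndarray:
    pts = as_polygon_array(polygon)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        raise GeometryError("zero-area polygon has no centroid")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def polygon_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Boolean raster mask of pixels whose centers lie inside the polygon.

    Membership uses the even-odd rule on pixel centers.  ``shape`` is the
    raster (height, width).  Evaluation is restricted to the polygon's
    bounding box for speed.
    """
    pts = as_polygon_array(polygon)
    h, w = shape
    x0 = max(int(np.floor(pts[:, 0].min())), 0)
    x1 = min(int(np.ceil(pts[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(pts[:, 1].min())), 0)
    y1 = min(int(np.ceil(pts[:, 1].max())) + 1, h)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    path = Path(pts)  # implicitly closed for point-in-polygon queries
    inside = path.contains_points(centers)
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


def _polygon_second_moments(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Area centroid and area-weighted covariance matrix of a polygon.

    Uses the exact Green's-theorem integrals over the polygon interior, so the
    result is independent of how densely the boundary is sampled (vertex-based
    PCA would not be).
    """
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        raise GeometryError("zero-area polygon has no principal axis")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    # second moments about the origin
    exx = ((x * x + x * xn + xn * xn) * cross).sum() / (12.0 * a)
    eyy = ((y * y + y * yn + yn * yn) * cross).sum() / (12.0 * a)
    exy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / (24.0 * a)
    cov = np.array([[exx - cx * cx, exy - cx * cy], [exy - cx * cy, eyy - cy * cy]])
    return np.array([cx, cy]), cov


def polygon_principal_axis(polygon) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit direction) of the polygon's major principal axis."""
    pts = as_polygon_array(polygon)
    centroid, cov = _polygon_second_moments(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    # canonical orientation: positive x (or positive y if vertical)
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return centroid, axis


def rotate_points(points, angle_deg: float, about=(0.0, 0.0)) -> np.ndarray:
    """Rotate points by ``angle_deg`` counter-clockwise about a pivot."""
    pts = np.asarray(points, dtype=float)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    about = np.asarray(about, dtype=float)
    return (pts - about) @ rot.T + about


def perpendicular_chord_length(polygon, point: np.ndarray, axis: np.ndarray) -> float:
    """Total length of the polygon's cross-section perpendicular to ``axis``
    through ``point``.  Concave shapes may intersect in several pieces; the
    piece lengths are summed."""
    poly = validate_simple_polygon(polygon)
    normal = np.array([-axis[1], axis[0]])
    span = 4.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1]) + 1.0
    line = LineString([point - span * normal, point + span * normal])
    inter = poly.intersection(line)
    return float(inter.length)
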