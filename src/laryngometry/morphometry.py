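"""Calibrated metric morphometry of the larynx and oropharyngeal inlet.

Seven parameters are produced from annotated polygons/landmarks plus a
pixel-to-millimetre scale: per-side vocal-fold length, midpoint width and
area; the vocal-fold angle at the anterior commissure; the glottic area;
the cross-sectional area of the oropharyngeal inlet (CSAOI); and the
retropalatal depth from laser-line triangulation.

Conventions (stated, since the clinical construction is not standardized):
fold *length* is the caliper extent of the fold polygon along its
area-weighted principal axis; *width* is the perpendicular cross-section
through the 50%-length point of that axis; areas are vertex-exact shoelace
areas scaled by mm_per_px².  Repeated evaluations are aggregated fieldwise
by their maximum, matching the clinical "best of at least three" protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationScale, LineSet, depth_from_line_offset
from .errors import GeometryError
from .geometry import (
    perpendicular_chord_length,
    polygon_principal_axis,
    validate_simple_polygon,
)

__all__ = [
    "MorphometryResult",
    "polygon_area_mm2",
    "vocal_fold_metrics",
    "vocal_angle",
    "retropalatal_depth",
    "aggregate_max",
    "percent_change",
]

_FIELDS = (
    "vocal_length_left_mm",
    "vocal_length_right_mm",
    "vocal_width_left_mm",
    "vocal_width_right_mm",
    "vocal_area_left_mm2",
    "vocal_area_right_mm2",
    "vocal_angle_deg",
    "glottic_area_mm2",
    "csaoi_mm2",
    "retropalatal_depth_mm",
)


@dataclass
class MorphometryResult:
    """The calibrated metric parameters of one image (fields may be absent)."""

    vocal_length_left_mm: float | None = None
    vocal_length_right_mm: float | None = None
    vocal_width_left_mm: float | None = None
    vocal_width_right_mm: float | None = None
    vocal_area_left_mm2: float | None = None
    vocal_area_right_mm2: float | None = None
    vocal_angle_deg: float | None = None
    glottic_area_mm2: float | None = None
    csaoi_mm2: float | None = None
    retropalatal_depth_mm: float | None = None

    def __post_init__(self):
        for name in _FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if name == "vocal_angle_deg":
                if not (0.0 <= v <= 180.0):
                    raise GeometryError("vocal angle must lie in [0, 180] degrees")
            elif v < 0:
                raise GeometryError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def polygon_area_mm2(polygon, scale: CalibrationScale) -> float:
    """Calibrated polygon area: shoelace area in px² times mm_per_px²."""
    poly = validate_simple_polygon(polygon)
    return float(poly.area) * scale.mm_per_px**2


def vocal_fold_metrics(polygon, scale: CalibrationScale) -> tuple[float, float, float]:
    """(length_mm, width_mm, area_mm2) of one vocal-fold polygon.

    Length is the extent of the vertex projections onto the polygon's major
    principal axis; width is the total chord length of the polygon cut
    perpendicular to that axis at 50% of the length.
    """
    poly = validate_simple_polygon(polygon)
    pts = np.asarray(polygon, float)
    centroid, axis = polygon_principal_axis(pts)
    t = (pts - centroid) @ axis
    tmin, tmax = float(t.min()), float(t.max())
    extent = tmax - tmin
    if extent <= 0:
        raise GeometryError("degenerate polygon: zero extent along principal axis")
    midpoint = centroid + (tmin + 0.5 * extent) * axis
    width_px = perpendicular_chord_length(pts, midpoint, axis)
    return (
        extent * scale.mm_per_px,
        width_px * scale.mm_per_px,
        float(poly.area) * scale.mm_per_px**2,
    )


def vocal_angle(anterior_commissure, left_process, right_process) -> float:
    """Interior angle (degrees) at the anterior commissure between the rays
    to the two vocal processes."""
    ac = np.asarray(anterior_commissure, float)
    u = np.asarray(left_process, float) - ac
    v = np.asarray(right_process, float) - ac
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("vocal-angle landmarks coincide")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(cosang)))


def retropalatal_depth(lines: LineSet, palate_offset_mm: float, posterior_wall_offset_mm: float) -> float:
    """Absolute retropalatal depth from the tilted-line offsets (mm)."""
    return abs(depth_from_line_offset(lines, palate_offset_mm, posterior_wall_offset_mm).depth_mm)


def aggregate_max(evaluations: list[MorphometryResult]) -> MorphometryResult:
    """Fieldwise maximum over repeated evaluations (None fields ignored)."""
    if not evaluations:
        raise ValueError("need at least one evaluation to aggregate")
    agg = {}
    for name in _FIELDS:
        vals = [getattr(e, name) for e in evaluations if getattr(e, name) is not None]
        agg[name] = max(vals) if vals else None
    return MorphometryResult(**agg)


def percent_change(pre_value: float, post_value: float, signed: bool = False) -> float:
    """Post-operative value as a percentage of the pre-operative baseline.

    Default convention sets the baseline to 100%, i.e. ``100 * post / pre``;
    with ``signed=True`` returns ``100 * (post - pre) / pre``.
    """
    if pre_value <= 0:
        raise ValueError("pre_value must be positive")
    if signed:
        return 100.0 * (post_value - pre_value) / pre_value
    return 100.0 * post_value / pre_value
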