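"""Calibrated morphometry: areas, fold metrics, angles, aggregation."""

import numpy as np
import pytest

from laryngometry import (
    CalibrationScale,
    MorphometryResult,
    PhantomConfig,
    aggregate_max,
    percent_change,
    polygon_area_mm2,
    vocal_angle,
    vocal_fold_metrics,
)
from laryngometry.calibration import detect_laser_dots, scale_from_dots
from laryngometry.errors import GeometryError
from laryngometry.geometry import polygon_mask, rotate_points
from laryngometry.phantom import generate_laryngeal_scene, random_laryngeal_config

SCALE_005 = CalibrationScale(mm_per_px=0.05)


def _square(size=20.0, origin=(10.0, 10.0)):
    x0, y0 = origin
    return np.array([[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size]])


def test_square_area():
    assert polygon_area_mm2(_square(), SCALE_005) == pytest.approx(1.0, rel=1e-12)


def test_area_rotation_invariant():
    rotated = rotate_points(_square(), 37.0, about=(20.0, 20.0))
    assert polygon_area_mm2(rotated, SCALE_005) == pytest.approx(1.0, abs=1e-9)


def test_area_pixel_counting_oracle(rng):
    """Shoelace area agrees with a fine-grid rasterization count."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=7))
    radii = rng.uniform(30, 60, size=7)
    poly = np.column_stack([100 + radii * np.cos(angles), 100 + radii * np.sin(angles)])
    exact = polygon_area_mm2(poly, CalibrationScale(mm_per_px=1.0))
    counted = polygon_mask((200, 200), poly).sum()  # unit-grid pixel centers
    assert counted == pytest.approx(exact, rel=0.02)


def test_too_few_vertices_rejected():
    with pytest.raises(GeometryError):
        polygon_area_mm2(np.array([[0.0, 0.0], [1.0, 1.0]]), SCALE_005)


def test_self_intersecting_polygon_rejected():
    bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
    with pytest.raises(GeometryError):
        polygon_area_mm2(bowtie, SCALE_005)


def test_rectangle_fold_metrics():
    rect = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 20.0], [0.0, 20.0]])
    length, width, area = vocal_fold_metrics(rect, SCALE_005)
    assert length == pytest.approx(5.0, rel=1e-9)
    assert width == pytest.approx(1.0, rel=1e-9)
    assert area == pytest.approx(5.0, rel=1e-9)


@pytest.mark.parametrize("angle", [13.0, 61.0, 118.0])
def test_fold_metrics_rotation_invariant(angle):
    rect = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 20.0], [0.0, 20.0]])
    rotated = rotate_points(rect, angle, about=(50.0, 10.0)) + 200.0
    length, width, area = vocal_fold_metrics(rotated, SCALE_005)
    assert length == pytest.approx(5.0, rel=0.01)
    assert width == pytest.approx(1.0, rel=0.01)
    assert area == pytest.approx(5.0, rel=0.01)


def test_metric_linearity_in_scale():
    rect = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 20.0], [0.0, 20.0]])
    l1, w1, a1 = vocal_fold_metrics(rect, CalibrationScale(mm_per_px=0.05))
    l2, w2, a2 = vocal_fold_metrics(rect, CalibrationScale(mm_per_px=0.15))
    assert (l2, w2) == pytest.approx((3 * l1, 3 * w1), rel=1e-12)
    assert a2 == pytest.approx(9 * a1, rel=1e-12)


def test_phantom_fold_width_recovered():
    cfg = PhantomConfig(fold_width_mm=3.0, seed=17)
    scene = generate_laryngeal_scene(cfg)
    scale = scale_from_dots(detect_laser_dots(scene.image), cfg.dot_separation_mm)
    _, width, _ = vocal_fold_metrics(scene.truth.regions["vocal_fold_left"], scale)
    assert width == pytest.approx(3.0, rel=0.05)


def test_randomized_phantom_recovery_median_error(rng):
    """Truth morphometry recovered within 5% median relative error."""
    errors = []
    for _ in range(10):
        cfg = random_laryngeal_config(rng)
        scene = generate_laryngeal_scene(cfg)
        scale = scale_from_dots(detect_laser_dots(scene.image), cfg.dot_separation_mm)
        truth = scene.truth.morphometry_mm
        length, width, area = vocal_fold_metrics(scene.truth.regions["vocal_fold_left"], scale)
        glottic = polygon_area_mm2(scene.truth.regions["glottis"], scale)
        for got, want in [
            (length, truth["vocal_length_mm"]),
            (width, truth["vocal_width_mm"]),
            (area, truth["vocal_area_mm2"]),
            (glottic, truth["glottic_area_mm2"]),
        ]:
            errors.append(abs(got - want) / want)
    assert np.median(errors) < 0.05


def test_symmetric_v_angle():
    ac = (0.0, 0.0)
    left = rotate_points(np.array([[0.0, 10.0]]), 10.0)[0]
    right = rotate_points(np.array([[0.0, 10.0]]), -10.0)[0]
    assert vocal_angle(ac, left, right) == pytest.approx(20.0, rel=1e-9)


def test_straight_line_angle_180():
    assert vocal_angle((0.0, 0.0), (1.0, 0.0), (-1.0, 0.0)) == pytest.approx(180.0)


def test_perpendicular_rays_angle_90():
    assert vocal_angle((0.0, 0.0), (1.0, 0.0), (0.0, 1.0)) == pytest.approx(90.0)


def test_coincident_landmarks_rejected():
    with pytest.raises(GeometryError):
        vocal_angle((1.0, 1.0), (1.0, 1.0), (2.0, 2.0))


def test_aggregate_single_identity():
    r = MorphometryResult(glottic_area_mm2=80.0)
    assert aggregate_max([r]) == r


def test_aggregate_max_of_three():
    rs = [MorphometryResult(glottic_area_mm2=v) for v in (80.0, 95.0, 90.0)]
    assert aggregate_max(rs).glottic_area_mm2 == 95.0


def test_aggregate_fields_maximized_independently():
    a = MorphometryResult(vocal_length_left_mm=10.0, vocal_area_left_mm2=20.0)
    b = MorphometryResult(vocal_length_left_mm=8.0, vocal_area_left_mm2=25.0)
    agg = aggregate_max([a, b])
    assert agg.vocal_length_left_mm == 10.0
    assert agg.vocal_area_left_mm2 == 25.0


def test_aggregate_idempotent_and_permutation_invariant():
    rs = [
        MorphometryResult(glottic_area_mm2=80.0, vocal_angle_deg=20.0),
        MorphometryResult(glottic_area_mm2=95.0, vocal_angle_deg=15.0),
    ]
    agg = aggregate_max(rs)
    assert aggregate_max([agg, agg]) == agg
    assert aggregate_max(rs[::-1]) == agg


def test_aggregate_empty_rejected():
    with pytest.raises(ValueError):
        aggregate_max([])


def test_percent_change_conventions():
    assert percent_change(100.0, 100.0) == 100.0
    assert percent_change(10.0, 5.0) == 50.0
    assert percent_change(10.0, 5.0, signed=True) == -50.0
    # clinical fold-width change: 2.96 -> 3.61 mm is a +21.96% signed change
    assert percent_change(2.96, 3.61, signed=True) == pytest.approx(21.96, abs=0.005)


def test_percent_change_requires_positive_baseline():
    with pytest.raises(ValueError):
        percent_change(0.0, 5.0)
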