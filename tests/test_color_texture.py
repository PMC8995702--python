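"""CIELab conversion, GLCM matrices/features and region profiles.

The GLCM implementation is checked against a brute-force pair-enumeration
oracle and against skimage's graycomatrix; CIELab against a hand-written
implementation of the CIE equations.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.feature import graycomatrix

from laryngometry import (
    GlcmParams,
    PhantomConfig,
    RegionAnnotation,
    generate_laryngeal_scene,
    glcm,
    region_profiles,
    rgb_to_cielab,
    texture_features,
)
from laryngometry.errors import GeometryError, RegionError
from laryngometry.color_texture import quantize

# ---------------------------------------------------------------- CIELab ----


def _cie_lab_reference(rgb):
    """Independent CIE sRGB -> XYZ (D65) -> Lab implementation."""
    rgb = np.asarray(rgb, float)
    lin = np.where(rgb > 0.04045, ((rgb + 0.055) / 1.055) ** 2.4, rgb / 12.92)
    m = np.array(
        [[0.412453, 0.357580, 0.180423],
         [0.212671, 0.715160, 0.072169],
         [0.019334, 0.119193, 0.950227]]
    )
    xyz = m @ lin
    white = m @ np.ones(3)  # D65 white = sRGB (1,1,1)
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    b = 200 * (f[1] - f[2])
    return L, a, b


def test_white_maps_to_L100():
    L, a, b = rgb_to_cielab((1.0, 1.0, 1.0))
    assert L == pytest.approx(100.0, abs=1e-6)
    assert a == pytest.approx(0.0, abs=1e-6)
    assert b == pytest.approx(0.0, abs=1e-6)


def test_black_maps_to_origin():
    assert rgb_to_cielab((0.0, 0.0, 0.0)) == pytest.approx((0.0, 0.0, 0.0), abs=1e-6)


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0.0, max_value=1.0))
def test_grays_stay_on_neutral_axis(g):
    L, a, b = rgb_to_cielab((g, g, g))
    assert abs(a) < 1e-6 and abs(b) < 1e-6


def test_lightness_strictly_increasing_in_gray():
    grays = np.linspace(0, 1, 21)
    Ls = [rgb_to_cielab((g, g, g))[0] for g in grays]
    assert np.all(np.diff(Ls) > 0)


@settings(derandomize=True, max_examples=50)
@given(st.tuples(*[st.floats(min_value=0.0, max_value=1.0)] * 3))
def test_cielab_matches_independent_cie_equations(rgb):
    got = rgb_to_cielab(rgb)
    expected = _cie_lab_reference(rgb)
    assert got == pytest.approx(expected, abs=5e-3)


def test_out_of_range_rgb_rejected():
    with pytest.raises(ValueError):
        rgb_to_cielab((1.2, 0.0, 0.0))


# ------------------------------------------------------------------ GLCM ----


def glcm_oracle(img, levels, offsets, symmetric):
    """Brute-force pair enumeration over every pixel and offset."""
    q = quantize(img, levels)
    h, w = q.shape
    out = np.zeros((levels, levels, len(offsets)))
    for k, (dy, dx) in enumerate(offsets):
        for y in range(h):
            for x in range(w):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    out[q[y, x], q[yy, xx], k] += 1
                    if symmetric:
                        out[q[yy, xx], q[y, x], k] += 1
        s = out[:, :, k].sum()
        if s > 0:
            out[:, :, k] /= s
    return out


def features_oracle(m):
    L = m.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    energy = (m**2).sum()
    contrast = ((i - j) ** 2 * m).sum()
    homog = (m / (1 + (i - j) ** 2)).sum()
    mu_i = (i * m).sum()
    mu_j = (j * m).sum()
    si = np.sqrt(((i - mu_i) ** 2 * m).sum())
    sj = np.sqrt(((j - mu_j) ** 2 * m).sum())
    corr = 1.0 if si * sj == 0 else ((i - mu_i) * (j - mu_j) * m).sum() / (si * sj)
    return energy, contrast, corr, homog


def test_two_by_two_worked_example():
    img = np.array([[0.0, 0.0], [0.6, 0.6]])
    params = GlcmParams(levels=2, offsets=((0, 1),), symmetric=True)
    m = glcm(img, params)[:, :, 0]
    assert m[0, 0] == pytest.approx(0.5)
    assert m[1, 1] == pytest.approx(0.5)
    assert m[0, 1] == m[1, 0] == 0.0
    energy, contrast, corr, homog = texture_features(m)
    assert (energy, contrast, homog, corr) == pytest.approx((0.5, 0.0, 1.0, 1.0))


def test_constant_image_degenerate_matrix():
    img = np.full((5, 5), 0.3)
    m = glcm(img, GlcmParams(levels=4, offsets=((0, 1),)))
    assert m[:, :, 0].sum() == pytest.approx(1.0)
    q = quantize(np.array([0.3]), 4)[0]
    assert m[q, q, 0] == pytest.approx(1.0)
    energy, contrast, corr, homog = texture_features(m)
    assert (energy, contrast, corr, homog) == pytest.approx((1.0, 0.0, 1.0, 1.0))


def test_uniform_matrix_energy():
    L = 4
    m = np.full((L, L), 1.0 / L**2)
    assert texture_features(m).energy == pytest.approx(1.0 / L**2)


def test_glcm_matches_bruteforce_oracle(rng):
    for _ in range(25):
        h, w = rng.integers(2, 17, size=2)
        levels = int(rng.integers(2, 9))
        img = rng.random((h, w))
        params = GlcmParams(levels=levels)
        got = glcm(img, params)
        want = glcm_oracle(img, levels, params.offsets, True)
        assert np.max(np.abs(got - want)) < 1e-12
        gf = texture_features(got)
        wf = np.mean([features_oracle(want[:, :, k]) for k in range(want.shape[2])], axis=0)
        assert np.max(np.abs(np.array([gf.energy, gf.contrast, gf.correlation, gf.homogeneity])
                             - wf[[0, 1, 2, 3]])) < 1e-12


def test_glcm_matches_skimage(rng):
    """Cross-check the horizontal offset against skimage's graycomatrix."""
    img = rng.random((12, 12))
    levels = 8
    q = quantize(img, levels).astype(np.uint8)
    sk = graycomatrix(q, distances=[1], angles=[0], levels=levels, symmetric=True, normed=True)
    ours = glcm(img, GlcmParams(levels=levels, offsets=((0, 1),), symmetric=True))[:, :, 0]
    assert np.allclose(ours, sk[:, :, 0, 0], atol=1e-12)


def test_contrast_invariant_under_transposition(rng):
    img = rng.random((10, 10))
    m = glcm(img, GlcmParams(levels=6, offsets=((0, 1),)))[:, :, 0]
    assert texture_features(m).contrast == pytest.approx(texture_features(m.T).contrast)


def test_feature_ranges_on_random_matrices(rng):
    L = 6
    for _ in range(1000):
        m = rng.random((L, L))
        m = (m + m.T) / 2
        m /= m.sum()
        f = texture_features(m)
        assert 0 < f.energy <= 1
        assert 0 < f.homogeneity <= 1
        assert f.contrast >= 0
        assert -1 <= f.correlation <= 1 + 1e-12


def test_unnormalized_matrix_rejected():
    with pytest.raises(ValueError):
        texture_features(np.ones((4, 4)))


def test_empty_region_rejected():
    with pytest.raises(RegionError):
        glcm(np.zeros((4, 4)), mask=np.zeros((4, 4), bool))


# -------------------------------------------------------- region profiles ----


def _square_annotation(label="interarytenoid", x0=2, y0=2, size=20):
    poly = np.array([[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size]], float)
    return RegionAnnotation(label=label, polygon=poly)


def test_uniform_red_region_profile():
    img = np.zeros((30, 30, 3))
    img[..., 0] = 1.0
    color, texture = region_profiles(img, _square_annotation())
    assert color.mean_R == pytest.approx(1.0)
    assert color.mean_G == color.mean_B == 0.0
    assert color.a_star > 0  # pure red sits on the +a* side
    assert texture.channels["R"].contrast == 0.0


def test_brighter_region_has_larger_lightness():
    dim = np.full((30, 30, 3), 0.3)
    bright = np.full((30, 30, 3), 0.7)
    ann = _square_annotation()
    assert region_profiles(bright, ann)[0].L_star > region_profiles(dim, ann)[0].L_star


def test_phantom_interarytenoid_contrast_rises_with_inflammation():
    lo = generate_laryngeal_scene(PhantomConfig(seed=21, inflammation=0.0))
    hi = generate_laryngeal_scene(PhantomConfig(seed=21, inflammation=1.0))
    ann_lo = RegionAnnotation("interarytenoid", lo.truth.regions["interarytenoid"])
    ann_hi = RegionAnnotation("interarytenoid", hi.truth.regions["interarytenoid"])
    c_lo = region_profiles(lo.image, ann_lo)[1].channels["R"].contrast
    c_hi = region_profiles(hi.image, ann_hi)[1].channels["R"].contrast
    assert c_hi > c_lo


def test_polygon_outside_raster_rejected():
    img = np.zeros((20, 20, 3))
    ann = RegionAnnotation("glottis", np.array([[30.0, 30.0], [40.0, 30.0], [35.0, 40.0]]))
    with pytest.raises(RegionError):
        region_profiles(img, ann)


def test_bad_region_label_rejected():
    with pytest.raises(GeometryError):
        RegionAnnotation("glotis", np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]]))


def test_self_intersecting_polygon_rejected():
    bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
    with pytest.raises(GeometryError):
        RegionAnnotation("glottis", bowtie)
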