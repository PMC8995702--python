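"""The weighted quadratic inflammation ("function") index.

For each image/region, three raw features are taken: a color term (the
region's a* red-green coordinate by default), GLCM contrast and GLCM
correlation (R channel by default, where mucosal inflammation is most
discriminative).  Each feature is min-max normalized across the cohort to
[0, 1] and combined as

    index = w_color * color² + w_contrast * contrast² + w_correlation * correlation²

with default weights 0.35 / 0.34 / 0.32, so scores lie in [0, 1.01].  The
normalization step is what makes the three terms commensurate before
squaring; a cohort of at least two profiles is therefore required.

:class:`InflammationIndexScorer` packages the cohort normalization (fit)
and scoring (transform) as a scikit-learn transformer so the index composes
with sklearn pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .color_texture import ColorProfile, TextureProfile
from .errors import ConfigError, RegionError

__all__ = [
    "IndexWeights",
    "NormalizedFeatures",
    "minmax_normalize",
    "function_index",
    "extract_index_features",
    "InflammationIndexScorer",
    "cohort_index",
]


@dataclass
class IndexWeights:
    w_color: float = 0.35
    w_contrast: float = 0.34
    w_correlation: float = 0.32

    def __post_init__(self):
        if self.w_color < 0 or self.w_contrast < 0 or self.w_correlation < 0:
            raise ConfigError("index weights must be non-negative")

    @property
    def total(self) -> float:
        return self.w_color + self.w_contrast + self.w_correlation


@dataclass
class NormalizedFeatures:
    """Normalized (color, contrast, correlation) triple with provenance."""

    color_n: float
    contrast_n: float
    correlation_n: float
    raw: tuple[float, float, float] | None = None
    cohort_min: tuple[float, float, float] | None = None
    cohort_max: tuple[float, float, float] | None = None


def minmax_normalize(values) -> np.ndarray:
    """Map values affinely onto [0, 1]; a constant input maps to all zeros."""
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def function_index(features, weights: IndexWeights | None = None) -> float:
    """Weighted quadratic index of a normalized feature triple in [0, 1]³."""
    weights = weights or IndexWeights()
    if isinstance(features, NormalizedFeatures):
        f = np.array([features.color_n, features.contrast_n, features.correlation_n])
    else:
        f = np.asarray(features, float)
    if f.shape != (3,):
        raise ValueError("expected a (color, contrast, correlation) triple")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("normalized features must lie in [0, 1]")
    w = np.array([weights.w_color, weights.w_contrast, weights.w_correlation])
    return float(np.dot(w, f**2))


def extract_index_features(
    profiles: list[tuple[ColorProfile, TextureProfile]],
    channel: str = "R",
    color_feature: str = "a_star",
) -> np.ndarray:
    """(n, 3) raw feature matrix [color, contrast(ch), correlation(ch)]."""
    rows = []
    for color, texture in profiles:
        if channel not in texture.channels:
            raise RegionError(f"texture profile has no channel {channel!r}")
        g = texture.channels[channel]
        rows.append([getattr(color, color_feature), g.contrast, g.correlation])
    return np.asarray(rows, float)


class InflammationIndexScorer(BaseEstimator, TransformerMixin):
    """Cohort-normalized function-index scorer (scikit-learn transformer).

    ``fit`` learns per-feature cohort minima/maxima from an (n, 3) raw
    feature matrix; ``transform`` min-max normalizes (clipping data outside
    the fitted range to [0, 1]) and returns the (n, 1) index scores.

    Parameters
    ----------
    w_color, w_contrast, w_correlation : float
        Non-negative index weights (defaults 0.35, 0.34, 0.32).
    """

    def __init__(self, w_color: float = 0.35, w_contrast: float = 0.34, w_correlation: float = 0.32):
        self.w_color = w_color
        self.w_contrast = w_contrast
        self.w_correlation = w_correlation

    def _weights(self) -> IndexWeights:
        return IndexWeights(self.w_color, self.w_contrast, self.w_correlation)

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n, 3) feature matrix [color, contrast, correlation]")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        return X

    def fit(self, X, y=None):
        X = self._check_X(X)
        if X.shape[0] < 2:
            raise ValueError("cohort normalization needs at least 2 samples")
        self._weights()  # validate
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = 3
        return self

    def transform_features(self, X) -> np.ndarray:
        """Normalized features in [0, 1] (constant cohort columns map to 0)."""
        X = self._check_X(X)
        span = self.data_max_ - self.data_min_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.data_min_[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)

    def transform(self, X) -> np.ndarray:
        f = self.transform_features(X)
        w = np.array([self.w_color, self.w_contrast, self.w_correlation])
        return (f**2 @ w)[:, None]

    def score_samples(self, X) -> np.ndarray:
        return self.transform(X).ravel()


def cohort_index(
    profiles: list[tuple[ColorProfile, TextureProfile]],
    weights: IndexWeights | None = None,
    channel: str = "R",
    color_feature: str = "a_star",
) -> np.ndarray:
    """Function-index score per profile, normalized across the cohort."""
    if len(profiles) < 2:
        raise ValueError("cohort_index needs at least 2 profiles")
    weights = weights or IndexWeights()
    X = extract_index_features(profiles, channel=channel, color_feature=color_feature)
    scorer = InflammationIndexScorer(weights.w_color, weights.w_contrast, weights.w_correlation)
    return scorer.fit(X).score_samples(X)
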