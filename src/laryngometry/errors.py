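"""Exception hierarchy used across the package."""


class LaryngometryError(Exception):
    """Base class for all package errors."""


class ConfigError(LaryngometryError):
    """Invalid configuration (rig parameters, phantom parameters, weights)."""


class GeometryError(LaryngometryError):
    """Degenerate or out-of-raster geometry (polygons, landmarks)."""


class DetectionError(LaryngometryError):
    """Laser fiducials could not be detected (unusable frame)."""


class CalibrationError(LaryngometryError):
    """Pixel-to-millimetre scale could not be established."""


class RegionError(LaryngometryError):
    """An annotated region is empty, missing, or outside the raster."""


class AnnotationParseError(LaryngometryError):
    """An annotation file violates the expected schema."""


class ImageReadError(LaryngometryError):
    """An image file is absent or unreadable."""
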