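"""File formats and rig configuration.

Images are PNG/TIFF/JPEG stills; 8- or 16-bit integer data are rescaled to
float RGB in [0, 1].  Annotations are JSON files of the form::

    {"image": "scene.png",
     "regions": [{"label": "glottis",
                  "polygon": [[x, y], ...],
                  "landmarks": {"anterior_commissure": [x, y], ...}}]}

Rig configuration (dot separation, line tilt, GLCM and index parameters)
loads from TOML or YAML.  Floats in CSV outputs are serialized at 9
significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .color_texture import GlcmParams, RegionAnnotation
from .errors import AnnotationParseError, ConfigError, ImageReadError
from .index import IndexWeights
from .phantom import PhantomScene

__all__ = [
    "RigConfig",
    "load_rig_config",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "write_scene",
    "truth_annotations",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.9g"


@dataclass
class RigConfig:
    """Laser-rig constants plus analysis parameters.

    Defaults reproduce the clinical rig: 1 mm dot separation, 8.5° line
    tilt, green (515 nm) laser.
    """

    dot_separation_mm: float = 1.0
    line_separation_mm: float = 10.0
    line_tilt_deg: float = 8.5
    laser_channel: str = "G"
    glcm: GlcmParams = field(default_factory=GlcmParams)
    index_weights: IndexWeights = field(default_factory=IndexWeights)
    index_channel: str = "R"
    index_color_feature: str = "a_star"
    seed: int = 0

    def __post_init__(self):
        if self.dot_separation_mm <= 0 or self.line_separation_mm <= 0:
            raise ConfigError("laser separations must be positive")
        if not (0.0 < self.line_tilt_deg < 90.0):
            raise ConfigError("line_tilt_deg must lie in (0, 90) degrees")
        if self.laser_channel not in {"R", "G", "B"}:
            raise ConfigError("laser_channel must be one of R, G, B")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_rig_config(path: str | Path) -> RigConfig:
    """Load a RigConfig from a .toml or .yaml/.yml file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raise ConfigError(f"unsupported config format: {path.suffix}")
    glcm = raw.pop("glcm", None)
    weights = raw.pop("index_weights", None)
    try:
        cfg = RigConfig(
            glcm=GlcmParams(**{**glcm, "offsets": tuple(map(tuple, glcm["offsets"]))})
            if glcm and "offsets" in glcm
            else (GlcmParams(**glcm) if glcm else GlcmParams()),
            index_weights=IndexWeights(**weights) if weights else IndexWeights(),
            **raw,
        )
    except TypeError as exc:
        raise ConfigError(f"bad config field: {exc}") from exc
    return cfg


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG still as float RGB in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageReadError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(float), 0.0, 1.0)
    raise ImageReadError(f"unsupported image dtype {arr.dtype} in {path}")


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0, 1] RGB raster as 8-bit PNG."""
    arr = np.clip(np.asarray(image, float), 0, 1)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def _require(obj: dict, key: str, context: str):
    if key not in obj:
        raise AnnotationParseError(f"missing field {key!r} in {context}")
    return obj[key]


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read and validate an annotation JSON file."""
    path = Path(path)
    if not path.exists():
        raise AnnotationParseError(f"annotation file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"invalid JSON in {path}: {exc}") from exc
    regions = _require(doc, "regions", str(path))
    if not isinstance(regions, list):
        raise AnnotationParseError(f"field 'regions' must be a list in {path}")
    out = []
    for i, reg in enumerate(regions):
        ctx = f"{path} regions[{i}]"
        label = _require(reg, "label", ctx)
        polygon = _require(reg, "polygon", ctx)
        if not isinstance(polygon, list) or len(polygon) < 3:
            raise AnnotationParseError(f"field 'polygon' needs >= 3 points in {ctx}")
        landmarks = reg.get("landmarks", {})
        try:
            out.append(RegionAnnotation(label=label, polygon=np.asarray(polygon, float),
                                        landmarks={k: np.asarray(v, float) for k, v in landmarks.items()}))
        except Exception as exc:
            raise AnnotationParseError(f"invalid region in {ctx}: {exc}") from exc
    return out


def write_annotations(path: str | Path, annotations: list[RegionAnnotation], image: str = "") -> None:
    doc = {
        "image": image,
        "regions": [
            {
                "label": a.label,
                "polygon": np.asarray(a.polygon, float).tolist(),
                "landmarks": {k: np.asarray(v, float).tolist() for k, v in a.landmarks.items()},
            }
            for a in annotations
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def truth_annotations(scene: PhantomScene) -> list[RegionAnnotation]:
    """Convert a phantom's ground-truth regions into annotation objects."""
    out = []
    for label, polygon in scene.truth.regions.items():
        landmarks = scene.truth.landmarks if label == "glottis" else {}
        out.append(RegionAnnotation(label=label, polygon=np.asarray(polygon), landmarks=landmarks))
    return out


def write_scene(scene: PhantomScene, out_dir: str | Path, stem: str) -> dict:
    """Write a scene as PNG + truth JSON + annotation JSON; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.png"
    write_image(img_path, scene.image)
    truth = scene.truth
    truth_doc = {
        "mm_per_px": truth.mm_per_px,
        "dot_centers": None if truth.dot_centers is None else truth.dot_centers.tolist(),
        "regions": {k: np.asarray(v).tolist() for k, v in truth.regions.items()},
        "landmarks": {k: np.asarray(v).tolist() for k, v in truth.landmarks.items()},
        "morphometry_mm": truth.morphometry_mm,
        "depth_offset_mm": truth.depth_offset_mm,
        "boundary_row": truth.boundary_row,
        "seed": scene.config.seed,
        "inflammation": scene.config.inflammation,
    }
    truth_path = out_dir / f"{stem}.truth.json"
    truth_path.write_text(json.dumps(truth_doc, indent=1))
    ann_path = out_dir / f"{stem}.annotations.json"
    if truth.regions:
        write_annotations(ann_path, truth_annotations(scene), image=img_path.name)
    return {"image": str(img_path), "truth": str(truth_path), "annotations": str(ann_path)}
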