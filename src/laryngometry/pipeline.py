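"""End-to-end analysis pipeline over a cohort manifest.

The manifest is a CSV with columns ``image``, ``annotations``, ``subject``,
``label`` (pre/post).  Per image the pipeline detects the dot fiducials,
derives the metric scale, extracts per-region color/texture features and
computes morphometry; per cohort it scores the inflammation index on the
interarytenoid region, runs ROC analysis against the labels, and tabulates
pre/post percent changes of the metric parameters.

Per-image failures are logged and skipped; the run fails only when more
than half of the images fail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import detect_laser_dots, scale_from_dots
from .classification import ThresholdScoreClassifier
from .color_texture import CHANNELS, region_profiles
from .errors import LaryngometryError
from .index import InflammationIndexScorer, extract_index_features
from .io import FLOAT_FORMAT, RigConfig, read_annotations, read_image
from .morphometry import MorphometryResult, percent_change, polygon_area_mm2, vocal_angle, vocal_fold_metrics

logger = logging.getLogger("laryngometry")

_PERCENT_FIELDS = (
    "glottic_area_mm2",
    "vocal_angle_deg",
    "vocal_width_left_mm",
    "vocal_width_right_mm",
    "vocal_area_left_mm2",
    "vocal_area_right_mm2",
)


@dataclass
class PipelineResult:
    calibration: pd.DataFrame
    features: pd.DataFrame
    morphometry: pd.DataFrame
    scores: pd.DataFrame
    roc: dict
    percent_changes: dict
    failures: list = field(default_factory=list)


def _feature_rows(subject, label, profiles) -> list[dict]:
    rows = []
    for region, (color, texture) in profiles.items():
        row = {
            "subject": subject,
            "label": label,
            "region": region,
            "mean_R": color.mean_R,
            "mean_G": color.mean_G,
            "mean_B": color.mean_B,
            "L_star": color.L_star,
            "a_star": color.a_star,
            "b_star": color.b_star,
            "pixel_count": color.pixel_count,
        }
        for ch, feats in texture.channels.items():
            for name, value in feats._asdict().items():
                row[f"{name}_{ch}"] = value
        rows.append(row)
    return rows


def analyze_image(image: np.ndarray, annotations, config: RigConfig):
    """Calibration, per-region profiles and morphometry for one still."""
    dots = detect_laser_dots(image)
    scale = scale_from_dots(dots, config.dot_separation_mm)
    profiles = {}
    morpho = {}
    for ann in annotations:
        if ann.label == "glottis":
            morpho["glottic_area_mm2"] = polygon_area_mm2(ann.polygon, scale)
            lm = ann.landmarks
            if {"anterior_commissure", "left_process", "right_process"} <= set(lm):
                morpho["vocal_angle_deg"] = vocal_angle(
                    lm["anterior_commissure"], lm["left_process"], lm["right_process"]
                )
            continue
        if ann.label == "oropharyngeal_inlet":
            morpho["csaoi_mm2"] = polygon_area_mm2(ann.polygon, scale)
            continue
        profiles[ann.label] = region_profiles(image, ann, config.glcm)
        if ann.label in ("vocal_fold_left", "vocal_fold_right"):
            side = ann.label.rsplit("_", 1)[1]
            length, width, area = vocal_fold_metrics(ann.polygon, scale)
            morpho[f"vocal_length_{side}_mm"] = length
            morpho[f"vocal_width_{side}_mm"] = width
            morpho[f"vocal_area_{side}_mm2"] = area
    return scale, profiles, MorphometryResult(**morpho)


def run_pipeline(config: RigConfig, manifest_path: str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("image", "annotations", "subject", "label"):
        if col not in manifest.columns:
            raise LaryngometryError(f"manifest is missing column {col!r}")

    cal_rows, feat_rows, morph_rows, failures = [], [], [], []
    per_image_profiles = []
    base = manifest_path.parent
    for _, row in manifest.iterrows():
        subject, label = row["subject"], row["label"]
        try:
            img_path = Path(row["image"])
            ann_path = Path(row["annotations"])
            image = read_image(img_path if img_path.is_absolute() else base / img_path)
            annotations = read_annotations(ann_path if ann_path.is_absolute() else base / ann_path)
            scale, profiles, morpho = analyze_image(image, annotations, config)
        except Exception as exc:  # noqa: BLE001 - any stage error is logged, run continues
            logger.warning("image %s (%s) failed: %s", row["image"], subject, exc)
            failures.append({"subject": subject, "image": row["image"], "error": str(exc)})
            continue
        cal_rows.append({"subject": subject, "label": label, "mm_per_px": scale.mm_per_px})
        feat_rows.extend(_feature_rows(subject, label, profiles))
        morph_rows.append({"subject": subject, "label": label, **morpho.as_dict()})
        per_image_profiles.append((subject, label, profiles))

    if len(failures) > 0.5 * len(manifest):
        raise LaryngometryError(f"{len(failures)}/{len(manifest)} images failed; aborting run")

    calibration = pd.DataFrame(cal_rows)
    features = pd.DataFrame(feat_rows)
    morphometry = pd.DataFrame(morph_rows)

    # cohort inflammation index on the interarytenoid region
    scores = pd.DataFrame()
    roc_summary: dict = {}
    ia = [(s, l, p["interarytenoid"]) for s, l, p in per_image_profiles if "interarytenoid" in p]
    if len(ia) >= 2:
        X = extract_index_features([p for _, _, p in ia], channel=config.index_channel,
                                   color_feature=config.index_color_feature)
        w = config.index_weights
        scorer = InflammationIndexScorer(w.w_color, w.w_contrast, w.w_correlation)
        vals = scorer.fit(X).score_samples(X)
        scores = pd.DataFrame(
            {
                "subject": [s for s, _, _ in ia],
                "label": [l for _, l, _ in ia],
                "color_raw": X[:, 0],
                "contrast_raw": X[:, 1],
                "correlation_raw": X[:, 2],
                "score": vals,
            }
        )
        labels = scores["label"].to_numpy()
        if len(np.unique(labels)) == 2:
            clf = ThresholdScoreClassifier(positive_label="post").fit(vals, labels)
            roc_summary = {
                "auc": clf.auc_,
                "cutoff": clf.cutoff_,
                "sensitivity": clf.sensitivity_,
                "specificity": clf.specificity_,
                "accuracy": clf.accuracy_,
                "n": int(len(vals)),
            }

    # pre/post percent change of cohort-mean morphometry
    percent_changes: dict = {}
    if not morphometry.empty and {"pre", "post"} <= set(morphometry["label"]):
        pre = morphometry[morphometry["label"] == "pre"]
        post = morphometry[morphometry["label"] == "post"]
        for col in _PERCENT_FIELDS:
            if col in morphometry and pre[col].notna().any() and post[col].notna().any():
                pre_mean, post_mean = pre[col].mean(), post[col].mean()
                if pre_mean > 0:
                    percent_changes[col] = {
                        "pre_mean": float(pre_mean),
                        "post_mean": float(post_mean),
                        "percent_of_baseline": percent_change(pre_mean, post_mean),
                        "signed_percent_change": percent_change(pre_mean, post_mean, signed=True),
                    }

    result = PipelineResult(
        calibration=calibration,
        features=features,
        morphometry=morphometry,
        scores=scores,
        roc=roc_summary,
        percent_changes=percent_changes,
        failures=failures,
    )
    if out_dir is not None:
        _write_bundle(result, config, out_dir)
    return result


def _write_bundle(result: PipelineResult, config: RigConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.calibration.to_csv(out / "calibration.csv", index=False, float_format=FLOAT_FORMAT)
    result.features.to_csv(out / "features.csv", index=False, float_format=FLOAT_FORMAT)
    result.morphometry.to_csv(out / "morphometry.csv", index=False, float_format=FLOAT_FORMAT)
    result.scores.to_csv(out / "scores.csv", index=False, float_format=FLOAT_FORMAT)
    (out / "roc.json").write_text(json.dumps(result.roc, indent=1))
    (out / "percent_changes.json").write_text(json.dumps(result.percent_changes, indent=1))
    versions = {"laryngometry": __version__, "numpy": np.__version__, "pandas": pd.__version__}
    log = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": versions,
        "n_failures": len(result.failures),
        "failures": result.failures,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
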