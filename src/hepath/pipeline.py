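"""End-to-end orchestration: detect ROIs, segment each, diagnose each.

The three trained stages travel as versioned model bundles (pickle files
with an embedded config and a content hash over their parameter arrays).
``run_pipeline`` executes the full flow on one slide and writes every
artifact under a run directory together with a manifest that suffices to
reproduce the run (config, seeds, model hashes).  ``train_all`` trains
whichever stages a dataset manifest provides data for.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import pickle
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .diagnosis import (
    CascadeModel,
    classify,
    extract_roi_features,
    feature_names,
    train_cascade,
    write_feature_csv,
)
from .pixel_classifiers import (
    build_segmentation_model,
    predict_pixel_labels,
    train_pixel_classifier,
)
from .roi import (
    DetectionResult,
    VisualDictionary,
    WindowClassifier,
    bag_histogram,
    build_dictionary,
    detect_rois,
    export_rois,
    make_training_pairs,
    train_window_classifier,
    word_descriptor,
    assign_words,
    EmptyWindowError,
)
from .segmentation import SuperpixelMap, TissueLabelMap, render_labels, slic_superpixels, superpixel_majority_vote
from .slide_io import (
    Rect,
    SlideImage,
    load_image,
    load_label_map,
    save_image,
    save_label_map,
    sliding_windows,
    tile_words,
)

logger = logging.getLogger(__name__)

BUNDLE_VERSION = 1


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters of the three stages plus model locations."""

    word_size: int = 120
    window: int = 3600
    overlap: int = 2400
    k: int = 64
    pos_overlap: float = 0.5
    near_margin: int | None = None  # None -> one window
    n_segments: int | None = None   # None -> pixel_count / pixels_per_segment
    pixels_per_segment: int = 3000
    compactness: float = 10.0
    seg_backend: str = "classical"
    patch_size: int = 384
    n_layers: int = 2
    feature_set: str = "both"
    downsample: int = 1
    seed: int = 0
    roi_model: str | None = None
    seg_model: str | None = None
    dx_model: str | None = None
    output_dir: str = "hepath_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------


def hash_arrays(arrays) -> str:
    """sha256 over a canonical byte serialization of numpy arrays."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def _bundle_arrays(kind: str, payload: dict):
    if kind == "roi":
        return (
            [payload["dictionary"].centroids]
            + [payload["classifier"].svm.support_vectors_,
               payload["classifier"].svm.dual_coef_,
               np.atleast_1d(payload["classifier"].svm.intercept_)]
        )
    if kind == "seg":
        return payload["model"].state_arrays()
    if kind == "dx":
        return payload["cascade"].stage_arrays()
    raise ValueError(f"unknown bundle kind {kind!r}")


def save_bundle(path: str, kind: str, payload: dict, config: PipelineConfig) -> str:
    """Write a versioned model bundle; returns its content hash."""
    digest = hash_arrays(_bundle_arrays(kind, payload))
    blob = {
        "format_version": BUNDLE_VERSION,
        "package_version": _pkg_version,
        "kind": kind,
        "hash": digest,
        "config": config.to_dict(),
        "payload": payload,
    }
    with open(path, "wb") as fh:
        pickle.dump(blob, fh)
    return digest


def load_bundle(path: str, kind: str | None = None) -> dict:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("format_version") != BUNDLE_VERSION:
        raise ConfigurationError(f"unsupported bundle version in {path}")
    if kind is not None and blob.get("kind") != kind:
        raise ConfigurationError(f"expected a {kind!r} bundle, got {blob.get('kind')!r}")
    return blob


# ---------------------------------------------------------------------------
# Stage training
# ---------------------------------------------------------------------------


def train_roi_stage(
    slides: list[tuple[SlideImage, list[Rect]]],
    config: PipelineConfig,
) -> dict:
    """Train dictionary + window classifier from slides with truth ROI rects."""
    near = config.near_margin if config.near_margin is not None else config.window
    descs = []
    per_slide = []
    for img, truth in slides:
        words = tile_words(img, config.word_size)
        d = np.array(
            [word_descriptor(img.pixels[r.y : r.y2, r.x : r.x2], config.word_size) for r in words]
        )
        descs.append(d)
        per_slide.append((img, truth, words, d))
    dictionary = build_dictionary(np.vstack(descs), k=config.k, seed=config.seed)
    pos_bags, neg_bags = [], []
    for img, truth, words, d in per_slide:
        assignments = assign_words(d, dictionary)
        windows = sliding_windows(img, config.window, config.overlap)
        pos_idx, neg_idx = make_training_pairs(truth, windows, near, config.pos_overlap)
        for idx, sink in ((pos_idx, pos_bags), (neg_idx, neg_bags)):
            for i in idx:
                try:
                    sink.append(bag_histogram(windows[i], words, assignments, dictionary.k))
                except EmptyWindowError:
                    continue
    classifier = train_window_classifier(pos_bags, neg_bags, seed=config.seed)
    return {"dictionary": dictionary, "classifier": classifier}


def train_seg_stage(patches, config: PipelineConfig, epochs: int = 30) -> dict:
    """Train the pixel classifier backend on (rgb, label) patches."""
    model = build_segmentation_model(
        backend=config.seg_backend, patch_size=config.patch_size, seed=config.seed
    )
    train_pixel_classifier(patches, model, epochs=epochs, seed=config.seed)
    return {"model": model}


def train_dx_stage(features: np.ndarray, labels: list[str], config: PipelineConfig) -> dict:
    cascade = train_cascade(np.asarray(features), labels, seed=config.seed)
    return {"cascade": cascade, "feature_set": config.feature_set, "n_layers": config.n_layers}


# ---------------------------------------------------------------------------
# train_all / run_pipeline
# ---------------------------------------------------------------------------


def train_all(manifest: dict | str, config: PipelineConfig, out_dir: str) -> dict:
    """Train every stage the manifest provides data for.

    Manifest keys (any non-empty subset):

    ``roi_slides``     — [{"image": path, "rois": [[x, y, w, h], ...]}]
    ``seg_patches``    — [{"image": path, "labels": path}]
    ``diagnosis_rois`` — [{"labels": path, "diagnosis": name}] (label maps
    are per-pixel tissue codes; superpixels are computed on the rendering)

    Returns {stage: {"path": bundle path, "hash": content hash}}.
    """
    if isinstance(manifest, str):
        with open(manifest) as fh:
            manifest = json.load(fh) if manifest.endswith(".json") else yaml.safe_load(fh)
    os.makedirs(out_dir, exist_ok=True)
    produced: dict[str, dict] = {}
    if manifest.get("roi_slides"):
        slides = [
            (load_image(e["image"]), [Rect(*map(int, r)) for r in e["rois"]])
            for e in manifest["roi_slides"]
        ]
        payload = train_roi_stage(slides, config)
        path = os.path.join(out_dir, "roi_model.pkl")
        produced["roi"] = {"path": path, "hash": save_bundle(path, "roi", payload, config)}
    if manifest.get("seg_patches"):
        patches = [
            (load_image(e["image"]).pixels, load_label_map(e["labels"]))
            for e in manifest["seg_patches"]
        ]
        payload = train_seg_stage(patches, config)
        path = os.path.join(out_dir, "seg_model.pkl")
        produced["seg"] = {"path": path, "hash": save_bundle(path, "seg", payload, config)}
    if manifest.get("diagnosis_rois"):
        feats, labels = [], []
        for e in manifest["diagnosis_rois"]:
            lab = TissueLabelMap(load_label_map(e["labels"]), granularity="pixel")
            sp = _superpixels_for_labels(lab, config)
            sp_lab = superpixel_majority_vote(lab, sp)
            feats.append(
                extract_roi_features(sp_lab, sp, config.feature_set, config.n_layers)
            )
            labels.append(e["diagnosis"])
        payload = train_dx_stage(np.array(feats), labels, config)
        path = os.path.join(out_dir, "dx_model.pkl")
        produced["dx"] = {"path": path, "hash": save_bundle(path, "dx", payload, config)}
    if not produced:
        raise ConfigurationError("manifest provides no training data for any stage")
    return produced


def _superpixels_for_labels(lab: TissueLabelMap, config: PipelineConfig) -> SuperpixelMap:
    # rendering the palette gives SLIC a color raster to cluster on
    rendered = render_labels(lab)
    return slic_superpixels(
        rendered,
        n_segments=config.n_segments,
        compactness=config.compactness,
        pixels_per_segment=config.pixels_per_segment,
    )


def run_pipeline(
    slide: str | SlideImage,
    config: PipelineConfig,
    roi_indices: list[int] | None = None,
) -> dict:
    """Fig-flow run: detect ROIs, segment each, diagnose each; write a manifest.

    ``roi_indices`` restricts segmentation/diagnosis to selected detections
    (default: all).  Per-ROI failures are logged, skipped, and recorded.
    """
    for name in ("roi_model", "seg_model", "dx_model"):
        path = getattr(config, name)
        if not path or not os.path.exists(path):
            raise ConfigurationError(f"missing model file for {name!r}: {path}")
    roi_blob = load_bundle(config.roi_model, "roi")
    seg_blob = load_bundle(config.seg_model, "seg")
    dx_blob = load_bundle(config.dx_model, "dx")
    img = load_image(slide) if isinstance(slide, str) else slide
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    t0 = time.time()
    result: DetectionResult = detect_rois(
        img,
        roi_blob["payload"]["dictionary"],
        roi_blob["payload"]["classifier"],
        word_size=config.word_size,
        window=config.window,
        overlap=config.overlap,
    )
    export_rois(img, result, os.path.join(out, "rois"))
    logger.info("ROI detection: %d boxes in %.1fs", len(result.boxes), time.time() - t0)
    selected = range(len(result.boxes)) if roi_indices is None else roi_indices
    fs = dx_blob["payload"].get("feature_set", config.feature_set)
    n_layers = dx_blob["payload"].get("n_layers", config.n_layers)
    rois_out = []
    feature_rows, feature_labels = [], []
    for i in selected:
        roi_dir = os.path.join(out, f"roi_{i:03d}")
        os.makedirs(roi_dir, exist_ok=True)
        try:
            crop = img.crop(result.boxes[i].window)
            lab = predict_pixel_labels(crop, seg_blob["payload"]["model"],
                                       patch_size=config.patch_size)
            sp = slic_superpixels(crop, n_segments=config.n_segments,
                                  compactness=config.compactness,
                                  pixels_per_segment=config.pixels_per_segment)
            sp_lab = superpixel_majority_vote(lab, sp)
            feats = extract_roi_features(sp_lab, sp, fs, n_layers)
            dx = classify(feats, dx_blob["payload"]["cascade"])
            save_label_map(lab.labels, os.path.join(roi_dir, "labels_pixel.png"))
            save_label_map(sp_lab.labels, os.path.join(roi_dir, "labels_superpixel.png"))
            save_image(render_labels(sp_lab), os.path.join(roi_dir, "rendered.png"))
            with open(os.path.join(roi_dir, "diagnosis.json"), "w") as fh:
                json.dump({"label": dx.label, "stage_scores": dx.stage_scores},
                          fh, indent=2, sort_keys=True)
            feature_rows.append(feats)
            feature_labels.append(dx.label)
            rois_out.append(
                {"index": i, "box": dataclasses.asdict(result.boxes[i].window),
                 "score": result.boxes[i].score, "diagnosis": dx.label,
                 "stage_scores": dx.stage_scores, "status": "ok"}
            )
        except Exception as exc:
            logger.exception("ROI %d failed", i)
            rois_out.append({"index": i, "status": "failed", "error": str(exc)})
    if feature_rows:
        write_feature_csv(os.path.join(out, "features.csv"), feature_rows,
                          feature_names(fs, n_layers), feature_labels)
    manifest = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "model_hashes": {"roi": roi_blob["hash"], "seg": seg_blob["hash"],
                         "dx": dx_blob["hash"]},
        "n_detected": len(result.boxes),
        "skipped_windows": result.skipped_windows,
        "rois": rois_out,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
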