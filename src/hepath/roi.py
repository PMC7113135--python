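"""Visual bag-of-words ROI detection.

A slide is cut into 120x120 "words"; each word is described by a CIELAB
color histogram concatenated with local-binary-pattern texture histograms
of its hematoxylin and eosin concentration channels.  k-means over word
descriptors yields a visual dictionary; a sliding analysis window is then a
bag — the histogram of its words' cluster ids — and a linear-margin
classifier separates diagnostically relevant windows from background.
Positive windows are merged into red-box region proposals.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import local_binary_pattern
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .slide_io import (
    Rect,
    SlideImage,
    WINDOW_OVERLAP,
    WINDOW_SIZE,
    WORD_SIZE,
    merge_overlapping,
    save_image,
    sliding_windows,
    tile_words,
)
from .stain import REFERENCE_STAINS, StainMatrix, deconvolve, rgb_to_lab

# Descriptor defaults: 8x8x8 CIELAB bins and 8-neighbor radius-1
# non-rotation-invariant uniform LBP (59 codes) per stain channel.
LAB_BINS = (8, 8, 8)
LBP_POINTS = 8
LBP_RADIUS = 1
LBP_BINS = 59
DEFAULT_K = 64
POS_OVERLAP = 0.5

_LAB_RANGES = ((0.0, 100.0), (-128.0, 128.0), (-128.0, 128.0))


class EmptyWindowError(ValueError):
    """A window contains no complete word."""


class InsufficientSamplesError(ValueError):
    """Fewer descriptors than requested clusters."""


class DegenerateTrainingError(ValueError):
    """Training data contains a single class."""


def descriptor_length(lab_bins=LAB_BINS, lbp_bins=LBP_BINS) -> int:
    return int(np.prod(lab_bins)) + 2 * lbp_bins


def word_descriptor(
    word_rgb: np.ndarray,
    word_size: int = WORD_SIZE,
    stains: StainMatrix = REFERENCE_STAINS,
    lab_bins=LAB_BINS,
) -> np.ndarray:
    """Color+texture descriptor of one word patch.

    The color histogram (CIELAB, ``lab_bins`` per axis, flattened) and the
    texture histogram (concatenated uniform-LBP code histograms of the H
    and E concentration channels) are each L1-normalized and concatenated.
    """
    patch = word_rgb.pixels if isinstance(word_rgb, SlideImage) else np.asarray(word_rgb)
    if patch.shape[0] != word_size or patch.shape[1] != word_size:
        raise ValueError(f"expected {word_size}x{word_size} patch, got {patch.shape[:2]}")
    lab = rgb_to_lab(patch)
    color_hist, _ = np.histogramdd(lab.reshape(-1, 3), bins=lab_bins, range=_LAB_RANGES)
    color_hist = color_hist.ravel()
    color_hist /= max(color_hist.sum(), 1.0)
    he = deconvolve(patch, stains)
    tex = []
    for ch in range(2):
        channel = np.clip(he[..., ch] * 127.5, 0, 255).astype(np.uint8)
        codes = local_binary_pattern(channel, LBP_POINTS, LBP_RADIUS, method="nri_uniform")
        hist = np.bincount(codes.astype(np.int64).ravel(), minlength=LBP_BINS)[:LBP_BINS]
        tex.append(hist.astype(float))
    tex_hist = np.concatenate(tex)
    tex_hist /= max(tex_hist.sum(), 1.0)
    return np.concatenate([color_hist, tex_hist])


@dataclass
class VisualDictionary:
    """k-means centroids over word descriptors, sorted for determinism."""

    centroids: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a k x d matrix with k >= 1")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def build_dictionary(descriptors: np.ndarray, k: int = DEFAULT_K, seed: int = 0) -> VisualDictionary:
    """k-means visual dictionary; centroids returned in lexicographic order."""
    x = np.asarray(descriptors, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("descriptors must be an n x d matrix")
    if x.shape[0] < k:
        raise InsufficientSamplesError(f"{x.shape[0]} descriptors < k={k}")
    if k == 1:
        return VisualDictionary(x.mean(axis=0, keepdims=True), seed=seed)
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    km.fit(x)
    centroids = km.cluster_centers_
    order = np.lexsort(centroids.T[::-1])
    return VisualDictionary(centroids[order], seed=seed)


def assign_word(descriptor: np.ndarray, dictionary: VisualDictionary) -> int:
    """Index of the nearest centroid; ties break toward the lowest index."""
    d = np.asarray(descriptor, dtype=np.float64)
    dist2 = np.sum((dictionary.centroids - d[None, :]) ** 2, axis=1)
    return int(np.argmin(dist2))


def assign_words(descriptors: np.ndarray, dictionary: VisualDictionary) -> np.ndarray:
    x = np.asarray(descriptors, dtype=np.float64)
    d2 = (
        np.sum(x**2, axis=1)[:, None]
        - 2 * x @ dictionary.centroids.T
        + np.sum(dictionary.centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


@dataclass
class BagFeature:
    """Word-cluster histogram of one analysis window."""

    window: Rect
    hist: np.ndarray
    n_words: int


def bag_histogram(
    window: Rect,
    word_rects: list[Rect],
    assignments: np.ndarray,
    k: int,
    normalize: bool = True,
) -> BagFeature:
    """Histogram of cluster ids over words fully contained in ``window``."""
    assignments = np.asarray(assignments)
    if len(word_rects) != len(assignments):
        raise ValueError("word_rects and assignments are misaligned")
    inside = [a for r, a in zip(word_rects, assignments) if window.contains(r)]
    if not inside:
        raise EmptyWindowError(f"window {window} contains no complete word")
    hist = np.bincount(np.asarray(inside), minlength=k).astype(float)
    n = len(inside)
    if normalize:
        hist /= n
    return BagFeature(window=window, hist=hist, n_words=n)


def make_training_pairs(
    roi_truth: list[Rect],
    windows: list[Rect],
    near_margin: int = WINDOW_SIZE,
    pos_overlap: float = POS_OVERLAP,
) -> tuple[list[int], list[int]]:
    """Window indices labeled positive (in an ROI) / negative (near one).

    A window is positive when its overlap with some truth ROI is at least
    ``pos_overlap`` of the window area; negative when it has zero truth
    overlap but its center lies within ``near_margin`` of a truth rect.
    Windows far from every ROI are left out of both sets.
    """
    pos, neg = [], []
    for i, wrect in enumerate(windows):
        overlaps = [wrect.intersection_area(t) for t in roi_truth]
        if any(o >= pos_overlap * wrect.area for o in overlaps):
            pos.append(i)
        elif all(o == 0 for o in overlaps):
            cx, cy = wrect.center
            if any(_point_rect_distance(cx, cy, t) <= near_margin for t in roi_truth):
                neg.append(i)
    return pos, neg


def _point_rect_distance(px: float, py: float, r: Rect) -> float:
    dx = max(r.x - px, px - r.x2, 0.0)
    dy = max(r.y - py, py - r.y2, 0.0)
    return float(np.hypot(dx, dy))


@dataclass
class WindowClassifier:
    """Margin classifier over bag histograms with a fixed decision threshold."""

    svm: SVC
    threshold: float = 0.0
    seed: int = 0

    def decision(self, hists: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(np.atleast_2d(hists))

    def predict(self, hists: np.ndarray) -> np.ndarray:
        return self.decision(hists) >= self.threshold


def _canonical_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample order independent of the caller's ordering (labels, then features)."""
    keys = np.column_stack([y.astype(float), x])
    return np.lexsort(keys.T[::-1])


def train_window_classifier(
    positive: list[BagFeature] | np.ndarray,
    negative: list[BagFeature] | np.ndarray,
    seed: int = 0,
    C: float = 1.0,
) -> WindowClassifier:
    """Linear-kernel SVM on bag histograms (positives = in-ROI windows)."""
    xp = _as_hist_matrix(positive)
    xn = _as_hist_matrix(negative)
    if xp.shape[0] == 0 or xn.shape[0] == 0:
        raise DegenerateTrainingError("need at least one sample of each class")
    x = np.vstack([xp, xn])
    y = np.concatenate([np.ones(xp.shape[0]), np.zeros(xn.shape[0])])
    order = _canonical_order(x, y)
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(x[order], y[order])
    return WindowClassifier(svm=svm, seed=seed)


def _as_hist_matrix(bags) -> np.ndarray:
    if isinstance(bags, np.ndarray):
        return np.atleast_2d(bags)
    return np.array([b.hist for b in bags]) if bags else np.zeros((0, 0))


@dataclass
class ROIBox:
    """A scored region proposal (merged from positive windows)."""

    window: Rect
    score: float
    is_roi: bool


@dataclass
class DetectionResult:
    boxes: list[ROIBox]
    window_boxes: list[ROIBox]
    overlay: SlideImage
    skipped_windows: int = 0


def detect_rois(
    img: SlideImage,
    dictionary: VisualDictionary,
    classifier: WindowClassifier,
    word_size: int = WORD_SIZE,
    window: int = WINDOW_SIZE,
    overlap: int = WINDOW_OVERLAP,
) -> DetectionResult:
    """Score every sliding window and merge positives into red-box proposals.

    Windows with no complete word (possible only at clamped borders or for
    undersized inputs) are skipped as negatives.  Inference is fully
    deterministic: no randomness is involved.
    """
    words = tile_words(img, word_size)
    descs = np.array([word_descriptor(img.pixels[r.y : r.y2, r.x : r.x2], word_size) for r in words])
    assignments = (
        assign_words(descs, dictionary) if len(words) else np.zeros(0, dtype=int)
    )
    window_boxes: list[ROIBox] = []
    skipped = 0
    for wrect in sliding_windows(img, window, overlap):
        try:
            bag = bag_histogram(wrect, words, assignments, dictionary.k)
        except EmptyWindowError:
            skipped += 1
            continue
        score = float(classifier.decision(bag.hist)[0])
        window_boxes.append(ROIBox(wrect, score, score >= classifier.threshold))
    positives = [b.window for b in window_boxes if b.is_roi]
    merged_rects = merge_overlapping(positives)
    boxes = []
    for mr in merged_rects:
        score = max(b.score for b in window_boxes if b.is_roi and b.window.intersects(mr))
        boxes.append(ROIBox(mr, score, True))
    overlay = _draw_boxes(img, [b.window for b in boxes])
    return DetectionResult(boxes=boxes, window_boxes=window_boxes, overlay=overlay,
                           skipped_windows=skipped)


def _draw_boxes(img: SlideImage, rects: list[Rect], thickness: int = 5) -> SlideImage:
    out = img.pixels.copy()
    red = np.array([255, 0, 0], dtype=np.uint8)
    for r in rects:
        t = thickness
        out[r.y : min(r.y + t, r.y2), r.x : r.x2] = red
        out[max(r.y2 - t, r.y) : r.y2, r.x : r.x2] = red
        out[r.y : r.y2, r.x : min(r.x + t, r.x2)] = red
        out[r.y : r.y2, max(r.x2 - t, r.x) : r.x2] = red
    return SlideImage(out)


def export_rois(img: SlideImage, result: DetectionResult, out_dir: str) -> list[str]:
    """Write each ROI crop as PNG plus a JSON sidecar of boxes and scores."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    meta = []
    for i, box in enumerate(result.boxes):
        p = os.path.join(out_dir, f"roi_{i:03d}.png")
        save_image(img.crop(box.window), p)
        paths.append(p)
        meta.append(
            {
                "index": i,
                "x": box.window.x,
                "y": box.window.y,
                "w": box.window.w,
                "h": box.window.h,
                "score": box.score,
            }
        )
    save_image(result.overlay, os.path.join(out_dir, "overlay.png"))
    with open(os.path.join(out_dir, "rois.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths
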