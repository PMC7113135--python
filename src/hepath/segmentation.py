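"""Tissue classes, SLIC superpixels, label transfer, and rendering.

The eight histopathologic tissue classes use the published integer codes
0, 2..8 (code 1 is reserved-unused and always rejected, never remapped):

====  =====================  ========
code  name                   display
====  =====================  ========
0     background             white
2     benign epithelium      magenta
3     malignant epithelium   blue
4     normal stroma          pink
5     desmoplastic stroma    violet
6     secretion              green
7     blood                  yellow
8     necrosis               red
====  =====================  ========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic as _skimage_slic

from .slide_io import DimensionError, SlideImage


class LabelError(ValueError):
    """A label code outside the published class set was encountered."""


@dataclass(frozen=True)
class TissueClass:
    code: int
    name: str
    color: tuple[int, int, int]


TISSUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass(0, "background", (255, 255, 255)),
    TissueClass(2, "benign_epithelium", (255, 0, 255)),
    TissueClass(3, "malignant_epithelium", (0, 0, 255)),
    TissueClass(4, "normal_stroma", (255, 192, 203)),
    TissueClass(5, "desmoplastic_stroma", (148, 0, 211)),
    TissueClass(6, "secretion", (0, 255, 0)),
    TissueClass(7, "blood", (255, 255, 0)),
    TissueClass(8, "necrosis", (255, 0, 0)),
)

CLASS_CODES: tuple[int, ...] = tuple(c.code for c in TISSUE_CLASSES)
CODE_TO_INDEX: dict[int, int] = {c.code: i for i, c in enumerate(TISSUE_CLASSES)}
CODE_TO_NAME: dict[int, str] = {c.code: c.name for c in TISSUE_CLASSES}
PALETTE: dict[int, tuple[int, int, int]] = {c.code: c.color for c in TISSUE_CLASSES}
EPITHELIUM_CODES: tuple[int, int] = (2, 3)
N_CLASSES = len(TISSUE_CLASSES)


def validate_codes(labels: np.ndarray) -> None:
    """Reject any raster containing a code outside {0, 2..8}."""
    bad = np.setdiff1d(np.unique(labels), np.array(CLASS_CODES))
    if bad.size:
        raise LabelError(f"invalid tissue class code(s) {bad.tolist()}; valid: {list(CLASS_CODES)}")


@dataclass
class TissueLabelMap:
    """Per-pixel or per-superpixel raster of tissue class codes."""

    labels: np.ndarray
    granularity: str = "pixel"  # "pixel" | "superpixel"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DimensionError(f"label map must be 2-D, got {self.labels.shape}")
        if self.granularity not in ("pixel", "superpixel"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        validate_codes(self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class SuperpixelMap:
    """H x W raster of superpixel ids, contiguous from 0, each 4-connected."""

    ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 2:
            raise DimensionError(f"superpixel map must be 2-D, got {self.ids.shape}")

    @property
    def n_superpixels(self) -> int:
        return int(self.ids.max()) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.ids.shape


def _enforce_connectivity(ids: np.ndarray) -> np.ndarray:
    """Relabel so each id is one 4-connected region, ids contiguous from 0.

    ``skimage.measure.label`` separates connected regions of equal value in
    one pass; ``background=-1`` keeps id 0 from being treated as background.
    """
    from skimage.measure import label as _cc_label

    return _cc_label(ids, connectivity=1, background=-1).astype(np.int64) - 1


def slic_superpixels(
    img: SlideImage | np.ndarray,
    n_segments: int | None = None,
    compactness: float = 10.0,
    pixels_per_segment: int = 3000,
) -> SuperpixelMap:
    """SLIC superpixels in CIELAB with spatial regularization.

    ``n_segments`` defaults to ``pixel_count / pixels_per_segment``.  Output
    ids partition the raster, are contiguous from 0, and each id is a single
    4-connected region (skimage's connectivity enforcement is followed by an
    exact relabeling pass).
    """
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img)
    n_pix = px.shape[0] * px.shape[1]
    if n_segments is None:
        n_segments = max(1, n_pix // pixels_per_segment)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > n_pix:
        raise ValueError(f"n_segments {n_segments} exceeds pixel count {n_pix}")
    if n_segments == 1:
        return SuperpixelMap(np.zeros(px.shape[:2], dtype=np.int64))
    # skimage's seeding grid can collapse tiny n_segments to a single
    # cluster; re-request at doubled density until the count contract
    # (S >= n_segments/2, floor 2) holds.
    target_min = max(2, -(-n_segments // 2))
    request = n_segments
    while True:
        ids = _skimage_slic(
            px,
            n_segments=request,
            compactness=compactness,
            start_label=0,
            enforce_connectivity=True,
            min_size_factor=0.25,
            channel_axis=-1,
        )
        ids = _enforce_connectivity(ids.astype(np.int64))
        if ids.max() + 1 >= target_min or request > 8 * n_segments:
            return SuperpixelMap(ids)
        request *= 2


def superpixel_majority_vote(pix: TissueLabelMap, sp: SuperpixelMap) -> TissueLabelMap:
    """Assign every pixel of a superpixel its modal class; ties -> lowest code.

    Implemented as one bincount over ``superpixel_id * n_classes + class``;
    the per-superpixel argmax over class *index* breaks ties toward the
    lowest code because codes are sorted.
    """
    if pix.shape != sp.shape:
        raise DimensionError(f"shape mismatch {pix.shape} vs {sp.shape}")
    n_sp = sp.n_superpixels
    class_idx = np.searchsorted(np.array(CLASS_CODES), pix.labels.ravel())
    counts = np.bincount(
        sp.ids.ravel() * N_CLASSES + class_idx, minlength=n_sp * N_CLASSES
    ).reshape(n_sp, N_CLASSES)
    modal_code = np.array(CLASS_CODES)[np.argmax(counts, axis=1)]
    return TissueLabelMap(modal_code[sp.ids], granularity="superpixel")


def superpixel_label_vector(lab: TissueLabelMap, sp: SuperpixelMap) -> np.ndarray:
    """One class code per superpixel id (requires a per-superpixel map)."""
    if lab.shape != sp.shape:
        raise DimensionError(f"shape mismatch {lab.shape} vs {sp.shape}")
    order = np.argsort(sp.ids.ravel(), kind="stable")
    first = np.searchsorted(sp.ids.ravel()[order], np.arange(sp.n_superpixels))
    return lab.labels.ravel()[order][first]


def render_labels(lab: TissueLabelMap) -> SlideImage:
    """Map codes to the display palette; inverse of :func:`parse_rendered`."""
    lut = np.zeros((max(CLASS_CODES) + 1, 3), dtype=np.uint8)
    for code, color in PALETTE.items():
        lut[code] = color
    return SlideImage(lut[lab.labels])


def parse_rendered(img: SlideImage) -> TissueLabelMap:
    """Recover a code map from a palette rendering (exact colors required)."""
    px = img.pixels
    out = np.full(px.shape[:2], -1, dtype=np.int64)
    for code, color in PALETTE.items():
        out[np.all(px == np.array(color, dtype=np.uint8), axis=-1)] = code
    if (out < 0).any():
        raise LabelError("image contains colors outside the tissue palette")
    return TissueLabelMap(out, granularity="pixel")


def mean_iou(pred: np.ndarray, truth: np.ndarray, codes: tuple[int, ...] = CLASS_CODES) -> float:
    """Mean intersection-over-union across the classes present in ``truth``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError(f"shape mismatch {pred.shape} vs {truth.shape}")
    ious = []
    for code in codes:
        t = truth == code
        if not t.any():
            continue
        p = pred == code
        inter = np.logical_and(p, t).sum()
        union = np.logical_or(p, t).sum()
        ious.append(inter / union)
    return float(np.mean(ious)) if ious else float("nan")
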