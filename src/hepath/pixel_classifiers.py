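"""Trainable per-pixel tissue classifiers and tiled whole-image inference.

Two interchangeable backends implement the ``PixelClassifier`` interface:

``EncoderDecoderClassifier``
    The convolutional encoder-decoder of :mod:`hepath.nn` (input-aware
    encoding, dense skips, multi-path decoding), trained with Adam on
    per-pixel cross-entropy.

``ClassicalPixelClassifier``
    A deterministic color/texture feature stack (RGB, CIELAB, H&E
    concentrations, multi-scale Gaussian means and local deviation) fed to
    an extremely randomized tree ensemble.  It is fast, needs little data,
    and serves as the reference backend for downstream modules.

Whole-image prediction tiles the raster into patch-sized tiles with 50%
overlap, averages class scores over overlaps, and takes the per-pixel
argmax (ties broken toward the lowest class code by argmax order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import ExtraTreesClassifier

from . import nn
from .segmentation import CLASS_CODES, LabelError, N_CLASSES, TissueLabelMap, validate_codes
from .slide_io import SlideImage
from .stain import REFERENCE_STAINS, deconvolve, rgb_to_lab


def _check_patch_labels(label_patches) -> None:
    for lab in label_patches:
        bad = np.setdiff1d(np.unique(lab), np.array(CLASS_CODES))
        if bad.size:
            raise LabelError(f"invalid tissue class code(s) {bad.tolist()} in training labels")


def _codes_to_indices(labels: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.array(CLASS_CODES), labels)


class EncoderDecoderClassifier:
    """CNN backend; see :mod:`hepath.nn` for the architecture."""

    backend = "espnet-style"

    def __init__(self, config: nn.SegNetConfig | None = None, seed: int = 0):
        self.config = config or nn.SegNetConfig(n_classes=N_CLASSES, class_codes=CLASS_CODES)
        self.seed = seed
        self.net = nn.EncoderDecoder(self.config, seed=seed)
        self.loss_trace: list[float] = []

    @property
    def patch_size(self) -> int:
        return self.config.patch_size

    def fit(self, rgb_patches, label_patches, epochs: int = 30, lr: float = 2e-3,
            batch_size: int = 4, seed: int | None = None):
        _check_patch_labels(label_patches)
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        x = np.stack([_to_net_input(p) for p in rgb_patches])      # (N,3,H,W)
        y = np.stack([_codes_to_indices(np.asarray(l)) for l in label_patches])
        n = x.shape[0]
        self.loss_trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.net.forward(x[idx])
                loss, _, dlogits = nn.softmax_cross_entropy(logits, y[idx])
                self.net.zero_grad()
                self.net.backward(dlogits)
                self.net.adam_step(lr=lr)
                epoch_loss += loss * len(idx)
            self.loss_trace.append(epoch_loss / n)
        return self

    def predict_scores(self, rgb: np.ndarray) -> np.ndarray:
        """Class scores (H,W,C) for one RGB tile (any /4-divisible pad handled)."""
        h, w = rgb.shape[:2]
        ph = (-h) % 4
        pw = (-w) % 4
        padded = np.pad(rgb, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        logits = self.net.forward(_to_net_input(padded)[None])[0]
        shifted = logits - logits.max(axis=0, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=0, keepdims=True)
        return probs.transpose(1, 2, 0)[:h, :w]

    def state_arrays(self):
        return self.net.state_arrays()


def _to_net_input(rgb: np.ndarray) -> np.ndarray:
    return np.asarray(rgb, dtype=np.float64).transpose(2, 0, 1) / 255.0


def pixel_features(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (H, W, 13) for the classical backend."""
    rgbf = np.asarray(rgb, dtype=np.float64)
    lab = rgb_to_lab(rgbf.astype(np.uint8))
    he = deconvolve(rgbf.astype(np.uint8), REFERENCE_STAINS)
    feats = [rgbf / 255.0, lab / 100.0, he]
    smooth1 = np.stack([ndimage.gaussian_filter(lab[..., i], 1.5) for i in range(3)], axis=-1)
    smooth3 = np.stack([ndimage.gaussian_filter(lab[..., i], 4.0) for i in range(3)], axis=-1)
    feats.append(smooth1 / 100.0)
    # local contrast: |L - smoothed L| captures texture scale
    feats.append(np.abs(lab - smooth3)[..., :1] / 100.0)
    feats.append(smooth3[..., :1] / 100.0)
    return np.concatenate(feats, axis=-1)


class ClassicalPixelClassifier:
    """Deterministic tree-ensemble backend over color/texture features."""

    backend = "classical"
    patch_size = 384  # tiling size only; the model itself is size-free

    def __init__(self, n_estimators: int = 40, max_pixels_per_patch: int = 2000,
                 seed: int = 0):
        self.n_estimators = n_estimators
        self.max_pixels_per_patch = max_pixels_per_patch
        self.seed = seed
        self.model: ExtraTreesClassifier | None = None
        self.loss_trace: list[float] = []

    def fit(self, rgb_patches, label_patches, epochs: int = 1, seed: int | None = None, **_):
        _check_patch_labels(label_patches)
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for rgb, lab in zip(rgb_patches, label_patches):
            f = pixel_features(rgb)
            f = f.reshape(-1, f.shape[-1])
            l = np.asarray(lab).ravel()
            take = min(self.max_pixels_per_patch, f.shape[0])
            idx = rng.choice(f.shape[0], size=take, replace=False)
            xs.append(f[idx])
            ys.append(l[idx])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        self.model = ExtraTreesClassifier(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1
        )
        self.model.fit(x, y)
        self.loss_trace = [1.0 - float(self.model.score(x, y))]
        return self

    def predict_scores(self, rgb: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        h, w = rgb.shape[:2]
        f = pixel_features(rgb)
        f = f.reshape(-1, f.shape[-1])
        proba = self.model.predict_proba(f)
        # Expand to the full 8-class axis in code order.
        out = np.zeros((h * w, N_CLASSES))
        for col, code in enumerate(self.model.classes_):
            out[:, CLASS_CODES.index(int(code))] = proba[:, col]
        return out.reshape(h, w, N_CLASSES)

    def state_arrays(self):
        if self.model is None:
            return []
        # Canonical summary of the fitted forest: per-tree structure arrays.
        arrays = []
        for est in self.model.estimators_:
            t = est.tree_
            arrays.extend([t.feature.copy(), t.threshold.copy(), t.value.copy()])
        return arrays


def build_segmentation_model(
    backend: str = "classical",
    n_classes: int = N_CLASSES,
    width: int = 8,
    n_stages: int = 2,
    patch_size: int = 384,
    seed: int = 0,
    **kwargs,
):
    """Construct an untrained pixel classifier of the requested backend."""
    if backend in ("espnet-style", "cnn"):
        cfg = nn.SegNetConfig(
            n_classes=n_classes, width=width, n_stages=n_stages,
            patch_size=patch_size, class_codes=CLASS_CODES,
        )
        return EncoderDecoderClassifier(cfg, seed=seed)
    if backend == "classical":
        return ClassicalPixelClassifier(seed=seed, **kwargs)
    raise ValueError(f"unknown backend {backend!r}")


def train_pixel_classifier(patches, model, epochs: int = 30, seed: int = 0):
    """Train a backend on (rgb_patch, label_patch) pairs.

    Returns the trained model; its ``loss_trace`` attribute holds the
    per-epoch training loss.  Label patches must use the published tissue
    codes; any other code (including the reserved 1) raises
    :class:`~hepath.segmentation.LabelError`.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("need at least one training patch")
    rgbs = [p[0] for p in patches]
    labs = [p[1] for p in patches]
    return model.fit(rgbs, labs, epochs=epochs, seed=seed)


def predict_pixel_labels(
    img: SlideImage | np.ndarray,
    model,
    patch_size: int | None = None,
    overlap_fraction: float = 0.5,
) -> TissueLabelMap:
    """Per-pixel tissue labels for an image of any size.

    The raster is tiled into ``patch_size`` squares advancing by
    ``patch_size * (1 - overlap_fraction)``; overlapping class scores are
    averaged before the argmax.  Images smaller than a patch are inferred
    whole (the backends reflect-pad internally as needed).
    """
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img)
    h, w = px.shape[:2]
    patch = patch_size or model.patch_size
    if h <= patch and w <= patch:
        scores = model.predict_scores(px)
        codes = np.array(CLASS_CODES)[np.argmax(scores, axis=-1)]
        return TissueLabelMap(codes, granularity="pixel")
    stride = max(1, int(round(patch * (1.0 - overlap_fraction))))
    ys = _tile_offsets(h, patch, stride)
    xs = _tile_offsets(w, patch, stride)
    acc = np.zeros((h, w, N_CLASSES))
    weight = np.zeros((h, w, 1))
    for y0 in ys:
        for x0 in xs:
            y1, x1 = min(y0 + patch, h), min(x0 + patch, w)
            acc[y0:y1, x0:x1] += model.predict_scores(px[y0:y1, x0:x1])
            weight[y0:y1, x0:x1] += 1.0
    codes = np.array(CLASS_CODES)[np.argmax(acc / weight, axis=-1)]
    return TissueLabelMap(codes, granularity="pixel")


def _tile_offsets(extent: int, patch: int, stride: int) -> list[int]:
    if extent <= patch:
        return [0]
    offs = list(range(0, extent - patch + 1, stride))
    if offs[-1] + patch < extent:
        offs.append(extent - patch)
    return offs
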