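"""Deterministic synthetic H&E-like data with known ground truth.

The generator emulates, at a cartoon level, the visual structure the
pipeline exploits in real biopsies: ducts are concentric disks (lumen
inside an epithelial ring), stroma fills the remainder, and the diagnosis
class controls the composition —

* ``benign``   — thin benign-epithelium rings, open (background) lumina,
  almost entirely normal stroma;
* ``atypia``   — thicker benign-epithelium rings, secretion-filled lumina,
  a modest desmoplastic-stroma fraction;
* ``DCIS``     — malignant-epithelium rings with central necrosis and a
  substantial desmoplastic fraction;
* ``invasive`` — small malignant rings plus scattered malignant islands in
  heavily desmoplastic stroma with blood specks.

Pixels are rendered as a per-class base color plus class-specific
sinusoidal texture and Gaussian noise, so color histograms *and* LBP
texture histograms carry class information.  Every artifact is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .segmentation import SuperpixelMap, TissueLabelMap
from .slide_io import Rect, SlideImage

DIAGNOSIS_CLASSES = ("benign", "atypia", "DCIS", "invasive")

#: Mean rendered RGB per tissue code (synthetic palette, loosely H&E-like).
TISSUE_RGB: dict[int, tuple[int, int, int]] = {
    0: (245, 245, 245),
    2: (140, 80, 170),
    3: (60, 50, 140),
    4: (235, 180, 190),
    5: (170, 120, 200),
    6: (205, 225, 170),
    7: (190, 55, 55),
    8: (215, 175, 135),
}

#: Sinusoidal texture cycles per 64 px and amplitude per tissue code.
TISSUE_TEXTURE: dict[int, tuple[float, float]] = {
    0: (0.0, 0.0),
    2: (9.0, 16.0),
    3: (13.0, 18.0),
    4: (3.0, 8.0),
    5: (5.0, 10.0),
    6: (1.5, 5.0),
    7: (7.0, 9.0),
    8: (2.0, 6.0),
}

#: Per-class duct/stroma recipe: (epithelium code, lumen code, desmoplastic
#: stroma fraction, duct count range, lumen radius range, ring width range).
CLASS_RECIPES: dict[str, dict] = {
    "benign": dict(epithelium=2, lumen=0, desmo=0.05, ducts=(2, 3),
                   lumen_r=(14, 20), ring_w=(5, 8), islands=0, blood=0),
    "atypia": dict(epithelium=2, lumen=6, desmo=0.20, ducts=(2, 3),
                   lumen_r=(10, 14), ring_w=(12, 16), islands=0, blood=0),
    "DCIS": dict(epithelium=3, lumen=8, desmo=0.45, ducts=(2, 3),
                 lumen_r=(12, 18), ring_w=(10, 14), islands=0, blood=1),
    "invasive": dict(epithelium=3, lumen=0, desmo=0.75, ducts=(1, 2),
                     lumen_r=(8, 11), ring_w=(6, 9), islands=12, blood=3),
}


class PlacementError(ValueError):
    """Requested structures cannot fit the canvas."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic ROI."""

    size: int = 256
    diagnosis: str = "benign"
    noise_sigma: float = 7.0
    desmo_fraction: float | None = None  # None -> class recipe value
    n_ducts: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSIS_CLASSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticROI:
    image: SlideImage
    truth: TissueLabelMap
    diagnosis: str
    duct_rings: list[dict] = field(default_factory=list)
    spec: SyntheticSpec | None = None


def _disk_mask(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _smooth_field(size: int, rng: np.random.Generator, scale: float = 12.0) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal((size, size)), scale)


def render_truth(truth: np.ndarray, rng: np.random.Generator,
                 noise_sigma: float = 7.0) -> SlideImage:
    """Render a code map into an RGB image with class texture and noise."""
    size_y, size_x = truth.shape
    yy, xx = np.mgrid[0:size_y, 0:size_x]
    img = np.zeros((size_y, size_x, 3))
    for code in np.unique(truth):
        mask = truth == code
        base = np.array(TISSUE_RGB[int(code)], dtype=float)
        freq, amp = TISSUE_TEXTURE[int(code)]
        tex = amp * np.sin(2 * np.pi * freq * (xx + 0.7 * yy) / 64.0) if freq else 0.0
        for ch in range(3):
            img[..., ch][mask] = base[ch] + (tex[mask] if freq else 0.0)
    img += rng.normal(0.0, noise_sigma, img.shape)
    return SlideImage(np.clip(np.round(img), 0, 255).astype(np.uint8))


def generate_roi(spec: SyntheticSpec) -> SyntheticROI:
    """One synthetic ROI with pixel truth and duct ring geometry."""
    rng = np.random.default_rng(spec.seed)
    recipe = CLASS_RECIPES[spec.diagnosis]
    size = spec.size
    desmo = recipe["desmo"] if spec.desmo_fraction is None else spec.desmo_fraction
    n_ducts = (
        int(rng.integers(recipe["ducts"][0], recipe["ducts"][1] + 1))
        if spec.n_ducts is None
        else spec.n_ducts
    )
    truth = np.full((size, size), 4, dtype=np.int64)
    # Desmoplastic stroma: threshold a smooth random field at the quantile
    # matching the requested fraction (so the measured fraction is exact on
    # the stroma region before ducts are stamped in).
    field_ = _smooth_field(size, rng)
    if desmo > 0:
        truth[field_ <= np.quantile(field_, desmo)] = 5
    # Place ducts on a jittered grid so they never overlap.
    max_r = int(recipe["lumen_r"][1] + recipe["ring_w"][1])
    margin = max_r + 4
    if 2 * margin >= size:
        raise PlacementError(f"ducts of radius {max_r} cannot fit a {size}px canvas")
    rings = []
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_ducts:
        attempts += 1
        if attempts > 500:
            raise PlacementError(f"cannot place {n_ducts} ducts on a {size}px canvas")
        cx = float(rng.uniform(margin, size - margin))
        cy = float(rng.uniform(margin, size - margin))
        if all((cx - ox) ** 2 + (cy - oy) ** 2 > (2.05 * max_r) ** 2 for ox, oy in centers):
            centers.append((cx, cy))
    for cx, cy in centers:
        lumen_r = float(rng.uniform(*recipe["lumen_r"]))
        ring_w = float(rng.uniform(*recipe["ring_w"]))
        outer = _disk_mask(size, cx, cy, lumen_r + ring_w)
        inner = _disk_mask(size, cx, cy, lumen_r)
        truth[outer] = recipe["epithelium"]
        truth[inner] = recipe["lumen"]
        rings.append(
            {"cx": cx, "cy": cy, "lumen_r": lumen_r, "ring_w": ring_w,
             "epithelium": recipe["epithelium"], "lumen": recipe["lumen"]}
        )
    for _ in range(recipe["islands"]):
        cx = float(rng.uniform(8, size - 8))
        cy = float(rng.uniform(8, size - 8))
        r = float(rng.uniform(3, 7))
        mask = _disk_mask(size, cx, cy, r)
        if not np.isin(truth[mask], (2, 3, recipe["lumen"])).any():
            truth[mask] = 3
    for _ in range(recipe["blood"]):
        cx = float(rng.uniform(8, size - 8))
        cy = float(rng.uniform(8, size - 8))
        mask = _disk_mask(size, cx, cy, float(rng.uniform(2, 4)))
        if not np.isin(truth[mask], (2, 3)).any():
            truth[mask] = 7
    image = render_truth(truth, rng, spec.noise_sigma)
    return SyntheticROI(
        image=image,
        truth=TissueLabelMap(truth, granularity="pixel"),
        diagnosis=spec.diagnosis,
        duct_rings=rings,
        spec=spec,
    )


def generate_dataset(
    n_per_class: int, base_spec: SyntheticSpec | None = None, seed: int = 0
) -> list[SyntheticROI]:
    """4 * n_per_class ROIs with per-ROI jittered specs, grouped by class."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec or SyntheticSpec()
    rois = []
    for ci, diagnosis in enumerate(DIAGNOSIS_CLASSES):
        for i in range(n_per_class):
            roi_seed = int((seed * 7919 + ci * 1009 + i) % (2**31 - 1))
            rois.append(generate_roi(replace(base, diagnosis=diagnosis, seed=roi_seed)))
    return rois


def split_dataset(
    rois: list[SyntheticROI], test_fraction: float = 0.25, seed: int = 0
) -> tuple[list[SyntheticROI], list[SyntheticROI]]:
    """Disjoint, exhaustive train/test split, stratified by diagnosis."""
    rng = np.random.default_rng(seed)
    train: list[SyntheticROI] = []
    test: list[SyntheticROI] = []
    for diagnosis in DIAGNOSIS_CLASSES:
        group = [r for r in rois if r.diagnosis == diagnosis]
        n_test = max(1, int(round(test_fraction * len(group)))) if group else 0
        idx = rng.permutation(len(group))
        for j, i in enumerate(idx):
            (test if j < n_test else train).append(group[i])
    return train, test


def generate_slide(
    canvas_size: int,
    roi_specs: list[SyntheticSpec],
    seed: int = 0,
    margin: int = 40,
) -> tuple[SlideImage, list[Rect]]:
    """White canvas with textured tissue blocks at recorded ground-truth rects."""
    rng = np.random.default_rng(seed)
    canvas = np.full((canvas_size, canvas_size, 3), 255, dtype=np.uint8)
    rois = [
        generate_roi(replace(spec, seed=int((seed * 6151 + spec.seed) % (2**31 - 1))))
        for spec in roi_specs
    ]
    # Jittered grid placement: blocks are assigned distinct grid cells, so
    # non-overlap is guaranteed whenever enough cells exist.
    max_size = max((r.image.width for r in rois), default=0)
    cell = max_size + 2 * margin
    n_cells_axis = (canvas_size - 2 * margin) // cell if cell else 0
    if n_cells_axis**2 < len(rois):
        raise PlacementError(
            f"{len(rois)} block(s) of size {max_size} cannot fit a "
            f"{canvas_size}px canvas without overlap"
        )
    cells = rng.permutation(n_cells_axis**2)[: len(rois)]
    rects: list[Rect] = []
    for roi, c in zip(rois, cells):
        size = roi.image.width
        cy, cx = divmod(int(c), n_cells_axis)
        slack = cell - size - 2 * margin
        x = margin + cx * cell + margin + (int(rng.integers(0, slack + 1)) if slack > 0 else 0)
        y = margin + cy * cell + margin + (int(rng.integers(0, slack + 1)) if slack > 0 else 0)
        canvas[y : y + size, x : x + size] = roi.image.pixels
        rects.append(Rect(x, y, size, size))
    return SlideImage(canvas), rects


# ---------------------------------------------------------------------------
# Concentric-ring fixture with an exact superpixel decomposition
# ---------------------------------------------------------------------------


def ring_fixture(
    size: int = 192,
    ring_width: int = 14,
    n_sectors: int = 8,
    ring_codes: tuple[int, ...] = (6, 3, 4, 5),
    noise_sigma: float = 4.0,
    seed: int = 0,
) -> dict:
    """A duct as exact concentric annuli, each split into angular-sector
    superpixels, with the ring index of every superpixel recorded.

    ``ring_codes[0]`` is the central lumen; ``ring_codes[1]`` the epithelial
    duct ring; subsequent codes the outward rings.  The outermost region
    (beyond the last ring) is background.  Returns image, truth,
    superpixel map, and per-ring superpixel id sets — the oracle for layer
    peeling.
    """
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - c + 0.5, yy - c + 0.5)
    theta = np.mod(np.arctan2(yy - c + 0.5, xx - c + 0.5), 2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi) * n_sectors).astype(np.int64), n_sectors - 1)
    n_rings = len(ring_codes)
    ring_idx = np.minimum((r / ring_width).astype(np.int64), n_rings)
    truth = np.zeros((size, size), dtype=np.int64)
    for i, code in enumerate(ring_codes):
        truth[ring_idx == i] = code
    sp_ids = np.where(ring_idx < n_rings, ring_idx * n_sectors + sector, -1)
    # Exterior background: one superpixel per sector as well.
    sp_ids = np.where(sp_ids < 0, n_rings * n_sectors + sector, sp_ids)
    ring_superpixels = [
        set(range(i * n_sectors, (i + 1) * n_sectors)) for i in range(n_rings + 1)
    ]
    rng = np.random.default_rng(seed)
    image = render_truth(truth, rng, noise_sigma)
    return {
        "image": image,
        "truth": TissueLabelMap(truth, granularity="pixel"),
        "superpixels": SuperpixelMap(sp_ids),
        "ring_superpixels": ring_superpixels,
        "ring_codes": ring_codes,
        "n_sectors": n_sectors,
    }
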