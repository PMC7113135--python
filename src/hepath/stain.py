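"""Color-space machinery: CIELAB conversion and Macenko stain deconvolution.

Optical density is defined as ``OD = -log10((I + eps) / 255)`` with
``eps = 1`` guarding ``log(0)``; any OD below zero (possible for I = 255
with the guard) is clipped.  Stain estimation follows Macenko's procedure:
keep pixels above an OD threshold, take the plane of the top two principal
OD directions, and read off robust extreme angles of the projected pixels.
Hematoxylin is identified as the stain direction with the larger
blue-channel OD weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab

from .slide_io import SlideImage

OD_EPS = 1.0
DEFAULT_OD_THRESHOLD = 0.15
DEFAULT_ANGLE_PERCENTILE = 1.0
DEFAULT_MAX_C_PERCENTILE = 99.0
MIN_TISSUE_PIXELS = 50


class InsufficientTissueError(ValueError):
    """Too few above-threshold optical-density pixels to estimate stains."""


class SingularStainError(ValueError):
    """Stain vectors are (near) collinear; deconvolution is ill-posed."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass
class StainMatrix:
    """Unit-norm optical-density directions for hematoxylin and eosin.

    ``max_concentrations`` stores the robust per-stain maximum concentration
    of the image the matrix was estimated from; it anchors normalization.
    """

    hematoxylin: np.ndarray
    eosin: np.ndarray
    max_concentrations: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.hematoxylin = _unit(np.asarray(self.hematoxylin, dtype=float))
        self.eosin = _unit(np.asarray(self.eosin, dtype=float))
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if np.any(self.hematoxylin < -1e-9) or np.any(self.eosin < -1e-9):
            raise ValueError("stain OD components must be non-negative")
        if abs(float(np.dot(self.hematoxylin, self.eosin))) > 1 - 1e-6:
            raise SingularStainError("stain vectors are collinear")

    @property
    def matrix(self) -> np.ndarray:
        """3 x 2 matrix with stain directions as columns (H, E)."""
        return np.stack([self.hematoxylin, self.eosin], axis=1)

    def to_dict(self) -> dict:
        return {
            "hematoxylin": self.hematoxylin.tolist(),
            "eosin": self.eosin.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainMatrix":
        return cls(
            np.array(d["hematoxylin"]),
            np.array(d["eosin"]),
            np.array(d.get("max_concentrations", [1.0, 1.0])),
        )


#: Package reference stains (Ruifrok-Johnston H&E OD directions), used when
#: per-image estimation is impossible (blank patches) and as the common
#: normalization target.
REFERENCE_STAINS = StainMatrix(
    hematoxylin=np.array([0.650, 0.704, 0.286]),
    eosin=np.array([0.072, 0.990, 0.105]),
    max_concentrations=np.array([1.9705, 1.0308]),
)


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel Beer-Lambert optical density, clipped to be non-negative."""
    od = -np.log10((pixels.astype(np.float64) + OD_EPS) / 255.0)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (up to the epsilon guard), as uint8."""
    intensity = 255.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - OD_EPS
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def rgb_to_lab(img: SlideImage | np.ndarray) -> np.ndarray:
    """sRGB (D65) to CIELAB; L in [0, 100], neutral grays at a = b = 0."""
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img)
    return rgb2lab(px)


def estimate_stains(
    img: SlideImage | np.ndarray,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    angle_percentile: float = DEFAULT_ANGLE_PERCENTILE,
    max_c_percentile: float = DEFAULT_MAX_C_PERCENTILE,
    min_tissue_pixels: int = MIN_TISSUE_PIXELS,
) -> StainMatrix:
    """Macenko estimation of the two stain directions of an H&E image."""
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img)
    od = rgb_to_od(px).reshape(-1, 3)
    tissue = od[np.all(od > od_threshold, axis=1)]
    if tissue.shape[0] < min_tissue_pixels:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} pixels above OD {od_threshold} "
            f"(need >= {min_tissue_pixels})"
        )
    # Plane of the top-2 principal directions of the OD point cloud.
    _, _, vt = np.linalg.svd(tissue - tissue.mean(axis=0), full_matrices=False)
    basis = vt[:2]  # 2 x 3
    # Orient basis vectors so projections land in a consistent half-plane.
    for i in range(2):
        if basis[i] @ tissue.mean(axis=0) < 0:
            basis[i] = -basis[i]
    proj = tissue @ basis.T  # N x 2
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100.0 - angle_percentile)
    v1 = basis.T @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis.T @ np.array([np.cos(hi), np.sin(hi)])
    v1 = _unit(np.maximum(v1, 0.0))
    v2 = _unit(np.maximum(v2, 0.0))
    # Hematoxylin carries more blue-channel OD.
    h, e = (v1, v2) if v1[2] > v2[2] else (v2, v1)
    stains = StainMatrix(h, e)
    conc = _concentrations(od.reshape(-1, 3), stains)
    stains.max_concentrations = np.percentile(conc, max_c_percentile, axis=0)
    return stains


def _concentrations(od_flat: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Least-squares unmixing of N x 3 OD rows onto the stain columns."""
    m = stains.matrix  # 3 x 2
    gram = m.T @ m
    if abs(np.linalg.det(gram)) < 1e-10:
        raise SingularStainError("degenerate stain matrix")
    sol = np.linalg.solve(gram, m.T @ od_flat.T).T  # N x 2
    return np.maximum(sol, 0.0)


def deconvolve(img: SlideImage | np.ndarray, stains: StainMatrix) -> np.ndarray:
    """H x W x 2 non-negative (hematoxylin, eosin) concentration raster."""
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img)
    od = rgb_to_od(px)
    conc = _concentrations(od.reshape(-1, 3), stains)
    return conc.reshape(px.shape[0], px.shape[1], 2)


def reconstruct(concentrations: np.ndarray, stains: StainMatrix) -> SlideImage:
    """Render a concentration raster back to RGB under the given stains."""
    conc = np.asarray(concentrations, dtype=np.float64)
    od = conc @ stains.matrix.T  # H x W x 3
    return SlideImage(od_to_rgb(od))


def normalize_stains(
    img: SlideImage | np.ndarray,
    stains: StainMatrix,
    reference: StainMatrix = REFERENCE_STAINS,
    max_c_percentile: float = DEFAULT_MAX_C_PERCENTILE,
) -> SlideImage:
    """Re-render ``img`` under reference stain vectors.

    Concentrations are unmixed with the image's own ``stains``, rescaled per
    stain so the robust maximum matches the reference's, then recombined
    with the reference directions.
    """
    conc = deconvolve(img, stains)
    maxc = np.percentile(conc.reshape(-1, 2), max_c_percentile, axis=0)
    scale = np.where(maxc > 1e-8, reference.max_concentrations / np.maximum(maxc, 1e-8), 1.0)
    return reconstruct(conc * scale, reference)


def angular_error_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two stain directions (sign-insensitive)."""
    c = abs(float(np.dot(_unit(np.asarray(v1, float)), _unit(np.asarray(v2, float)))))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
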