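"""Raster I/O, coordinate conventions, and tiling geometry.

Coordinates are 0-based with ``x`` the column and ``y`` the row; all
rectangles are half-open ``[x, x+w) x [y, y+h)``.  Images are H x W x 3
uint8 RGB rasters wrapped in :class:`SlideImage`; label maps are
single-channel integer rasters written as PNG/TIFF.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Side length of a visual "word" patch in pixels.
WORD_SIZE = 120
#: Side length of a sliding analysis window in pixels.
WINDOW_SIZE = 3600
#: Overlap between consecutive sliding windows in pixels.
WINDOW_OVERLAP = 2400

_RASTER_EXTS = {".tif", ".tiff", ".jpg", ".jpeg", ".bmp", ".png"}


class FormatError(ValueError):
    """Raised when a file cannot be decoded as a supported raster."""


class DimensionError(ValueError):
    """Raised when raster/rect dimensions violate a contract."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open pixel interval."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.w < 0 or self.h < 0:
            raise DimensionError(f"negative rect geometry: {self}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def contains(self, other: "Rect") -> bool:
        """True when ``other`` lies fully inside this rect."""
        return (
            other.x >= self.x
            and other.y >= self.y
            and other.x2 <= self.x2
            and other.y2 <= self.y2
        )

    def intersection_area(self, other: "Rect") -> int:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        return max(iw, 0) * max(ih, 0)

    def intersects(self, other: "Rect") -> bool:
        return self.intersection_area(other) > 0

    def union_box(self, other: "Rect") -> "Rect":
        x = min(self.x, other.x)
        y = min(self.y, other.y)
        return Rect(x, y, max(self.x2, other.x2) - x, max(self.y2, other.y2) - y)


@dataclass
class SlideImage:
    """RGB raster plus nominal-magnification metadata.

    ``pixels`` is always H x W x 3 uint8.  A ``magnification_hint`` other
    than 40 is accepted with a logged warning: the pipeline's defaults are
    calibrated for x40 scans and results at other scales may degrade.
    """

    pixels: np.ndarray
    magnification_hint: float | None = None
    path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DimensionError(f"expected H x W x 3 raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"zero-area image: shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise DimensionError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.magnification_hint is not None and self.magnification_hint != 40:
            logger.warning(
                "image %s has nominal magnification x%s; defaults assume x40",
                self.path or "<memory>",
                self.magnification_hint,
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def crop(self, rect: Rect) -> "SlideImage":
        if rect.x2 > self.width or rect.y2 > self.height:
            raise DimensionError(f"rect {rect} exceeds image {self.width}x{self.height}")
        return SlideImage(self.pixels[rect.y : rect.y2, rect.x : rect.x2])


def load_image(path: str | os.PathLike, magnification_hint: float | None = None) -> SlideImage:
    """Decode a TIFF/JPEG/BMP/PNG file into a :class:`SlideImage`.

    Grayscale rasters are replicated to three channels; an alpha channel is
    dropped.  Unsupported or undecodable files raise :class:`FormatError`.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _RASTER_EXTS:
        raise FormatError(f"unsupported raster extension {ext!r} (expected TIFF/JPEG/BMP/PNG)")
    try:
        if ext in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # decoder-specific exception types vary
        raise FormatError(f"cannot decode {ext!r} file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unsupported raster layout {arr.shape} in {path}")
    if arr.size == 0:
        raise DimensionError(f"zero-area image in {path}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return SlideImage(arr, magnification_hint=magnification_hint, path=path)


def save_image(img: SlideImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB raster as PNG/JPEG/BMP/TIFF, chosen by extension."""
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img, dtype=np.uint8)
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def load_label_map(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel integer label raster (PNG or TIFF)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    arr = tifffile.imread(path) if ext in (".tif", ".tiff") else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"label map must be single-channel, got shape {arr.shape}")
    return arr.astype(np.int64)


def save_label_map(labels: np.ndarray, path: str | os.PathLike) -> None:
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise DimensionError(f"label map must be 2-D, got shape {labels.shape}")
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    out = labels.astype(np.uint8)
    if tuple(np.unique(labels)) and labels.max() > 255:
        out = labels.astype(np.uint16)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def tile_words(img: SlideImage | tuple[int, int], word_size: int = WORD_SIZE) -> list[Rect]:
    """Non-overlapping ``word_size`` grid anchored at (0, 0).

    Partial border tiles are discarded, so the count is
    ``floor(W/word_size) * floor(H/word_size)``; an image smaller than one
    word in either dimension yields an empty list.
    """
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    w, h = _extent(img)
    return [
        Rect(ix * word_size, iy * word_size, word_size, word_size)
        for iy in range(h // word_size)
        for ix in range(w // word_size)
    ]


def sliding_windows(
    img: SlideImage | tuple[int, int],
    window: int = WINDOW_SIZE,
    overlap: int = WINDOW_OVERLAP,
) -> list[Rect]:
    """Overlapping square analysis windows covering every pixel.

    Windows advance by ``stride = window - overlap``; when the last stride
    position would overrun the image, a final window is clamped to end at
    the image edge.  An image smaller than ``window`` in either dimension
    produces one window covering the whole image (callers may treat it as
    undersized via :func:`is_undersized_window`).
    """
    if not 0 <= overlap < window:
        raise ValueError(f"require 0 <= overlap < window, got {overlap}/{window}")
    w, h = _extent(img)
    if w < window or h < window:
        return [Rect(0, 0, w, h)]
    stride = window - overlap
    xs = _axis_offsets(w, window, stride)
    ys = _axis_offsets(h, window, stride)
    return [Rect(x, y, window, window) for y in ys for x in xs]


def is_undersized_window(rect: Rect, window: int = WINDOW_SIZE) -> bool:
    """True for the flagged whole-image window returned for small inputs."""
    return rect.w != window or rect.h != window


def _axis_offsets(extent: int, window: int, stride: int) -> list[int]:
    offsets = list(range(0, extent - window + 1, stride))
    if offsets[-1] + window < extent:
        offsets.append(extent - window)
    return offsets


def _extent(img: SlideImage | tuple[int, int]) -> tuple[int, int]:
    if isinstance(img, SlideImage):
        return img.width, img.height
    w, h = img
    return int(w), int(h)


def merge_overlapping(rects: list[Rect]) -> list[Rect]:
    """Union-find merge of overlapping rects into connected bounding boxes.

    Merging is transitive: the bounding boxes of connected components of
    the pairwise-overlap graph are returned, sorted by (y, x).
    """
    n = len(rects)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if rects[i].intersects(rects[j]):
                parent[find(i)] = find(j)
    groups: dict[int, Rect] = {}
    for i, r in enumerate(rects):
        root = find(i)
        groups[root] = r if root not in groups else groups[root].union_box(r)
    return sorted(groups.values(), key=lambda r: (r.y, r.x))
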