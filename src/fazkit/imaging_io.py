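"""Raster and region I/O plus the shared geometric data model.

Coordinate convention used throughout the package: 0-based, row-major
``(row, col)`` indices with pixel centers at integer coordinates.  The
physical scale of an en face scan is carried as ``mm_per_pixel``; the
default corresponds to a 3 mm x 3 mm macular scan exported at
1024 x 1024 px.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile
from PIL import Image

#: physical scale of a 3 mm scan exported at 1024 px
DEFAULT_MM_PER_PIXEL = 3.0 / 1024.0

# ITU-R 601 luminance weights, the standard grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


class ImagingError(ValueError):
    """Raised for unreadable files, degenerate polygons and geometry mismatches."""


@dataclass
class EnFaceImage:
    """A 2D grayscale en face angiography raster with physical scale.

    Parameters
    ----------
    pixels:
        2D uint8 array, intensities in [0, 255].
    mm_per_pixel:
        Physical size of one pixel side in millimetres.
    eye_id:
        Opaque identifier of the imaged eye.
    axial_length_mm:
        Optional measured axial length, used for magnification correction.
    """

    pixels: np.ndarray
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    eye_id: Optional[str] = None
    axial_length_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImagingError("EnFaceImage requires a 2D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ImagingError("EnFaceImage must be at least 64x64 px")
        if self.pixels.dtype != np.uint8:
            arr = self.pixels
            if arr.min() < 0 or arr.max() > 255:
                raise ImagingError("intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if not self.mm_per_pixel > 0:
            raise ImagingError("mm_per_pixel must be positive")
        if self.axial_length_mm is not None and not self.axial_length_mm > 0:
            raise ImagingError("axial_length_mm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        return replace(self, pixels=pixels)


@dataclass
class RegionMask:
    """A binary region raster (FAZ / label representation).

    Foreground is stored as boolean ``True``; serialized as 255 on 0.
    Geometry fields mirror :class:`EnFaceImage` so a mask can annotate an
    image one-to-one.
    """

    pixels: np.ndarray
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    eye_id: Optional[str] = None
    axial_length_mm: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ImagingError("RegionMask requires a 2D array")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, [0, 1, 255])):
                raise ImagingError("mask values must be binary (0/255 or bool)")
            arr = arr > 0
        self.pixels = arr
        if not self.mm_per_pixel > 0:
            raise ImagingError("mm_per_pixel must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.sum())

    def to_uint8(self) -> np.ndarray:
        """Serialized form: background 0, region 255."""
        return np.where(self.pixels, 255, 0).astype(np.uint8)

    def with_pixels(self, pixels: np.ndarray) -> "RegionMask":
        return replace(self, pixels=pixels)


@dataclass
class RoiPolygon:
    """Closed polygon region-of-interest in (row, col) pixel coordinates."""

    vertices: np.ndarray
    eye_id: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ImagingError("vertices must be an (n, 2) array of (row, col)")
        if len(np.unique(v, axis=0)) < 3:
            raise ImagingError("polygon needs at least 3 distinct vertices")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Linear min-max rescale of higher-bit-depth data to [0, 255]."""
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        # constant frame: scale by the nominal dtype range instead
        return np.full(arr.shape, round(lo * 255.0 / 65535.0) if lo > 255 else lo,
                       dtype=np.uint8)
    return np.round((arr - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def read_image(
    path,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    metadata: Optional[Mapping] = None,
) -> EnFaceImage:
    """Read a PNG or TIFF en face export as an 8-bit grayscale image.

    Multi-channel inputs are converted by standard luminance weighting;
    16-bit inputs are linearly rescaled to 0-255.
    """
    path = Path(path)
    if not path.exists():
        raise ImagingError(f"no such file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ImagingError(f"unreadable image {path}: {exc}") from exc
    if arr.size == 0:
        raise ImagingError(f"zero-size image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
        arr = np.round(np.clip(arr, 0, None))
        if arr.max() > 255:
            arr = _to_uint8(arr)
        arr = arr.astype(np.uint8)
    elif arr.ndim != 2:
        raise ImagingError(f"expected a 2D image, got shape {arr.shape}")
    meta = dict(metadata or {})
    return EnFaceImage(
        pixels=_to_uint8(arr),
        mm_per_pixel=mm_per_pixel,
        eye_id=meta.get("eye_id"),
        axial_length_mm=meta.get("axial_length_mm"),
    )


def write_image(obj, path) -> Path:
    """Write an :class:`EnFaceImage` or :class:`RegionMask` as 8-bit PNG/TIFF."""
    path = Path(path)
    arr = obj.to_uint8() if isinstance(obj, RegionMask) else np.asarray(obj.pixels)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)
    return path


def _even_odd_inside(rows: np.ndarray, cols: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    ``rows``/``cols`` are broadcastable coordinate arrays of pixel centers.
    """
    inside = np.zeros(np.broadcast(rows, cols).shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if r1 == r2:
            continue  # horizontal edge never crosses a horizontal ray's level
        crosses = (r1 > rows) != (r2 > rows)
        x_at = (c2 - c1) * (rows - r1) / (r2 - r1) + c1
        inside ^= crosses & (cols < x_at)
    return inside


def polygon_to_mask(
    poly: RoiPolygon,
    height: int,
    width: int,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
) -> RegionMask:
    """Rasterize a polygon ROI: pixel centers inside (even-odd rule) become foreground."""
    v = poly.vertices
    if (v[:, 0].min() < -0.5 or v[:, 0].max() > height - 0.5
            or v[:, 1].min() < -0.5 or v[:, 1].max() > width - 0.5):
        raise ImagingError("polygon extends outside the raster bounds")
    rows = np.arange(height, dtype=float)[:, None]
    cols = np.arange(width, dtype=float)[None, :]
    inside = _even_odd_inside(rows, cols, v)
    return RegionMask(inside, mm_per_pixel=mm_per_pixel, eye_id=poly.eye_id)


def mask_to_polygon(mask: RegionMask) -> RoiPolygon:
    """Trace the boundary polygon of a single-component mask.

    The returned polygon re-rasterizes (via :func:`polygon_to_mask`) to a
    region with Jaccard >= 0.99 against the source for components of
    >= 100 px.
    """
    from scipy import ndimage
    from skimage import measure

    m = mask.pixels
    if not m.any():
        raise ImagingError("cannot trace an empty mask")
    _, n_comp = ndimage.label(m, structure=np.ones((3, 3), int))
    if n_comp != 1:
        raise ImagingError(f"mask has {n_comp} components; expected exactly 1")
    padded = np.pad(m.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo the pad offset
    return RoiPolygon(contour, eye_id=mask.eye_id)


def save_roi_json(poly: RoiPolygon, path) -> Path:
    """Serialize an ROI as ``{"eye_id": ..., "vertices": [[r, c], ...]}``."""
    path = Path(path)
    payload = {"eye_id": poly.eye_id, "vertices": poly.vertices.tolist()}
    path.write_text(json.dumps(payload))
    return path


def load_roi_json(path) -> RoiPolygon:
    data = json.loads(Path(path).read_text())
    return RoiPolygon(np.asarray(data["vertices"], dtype=float), eye_id=data.get("eye_id"))
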