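"""Dataset factory: chunked stack extraction, label images, amplification, export.

Turns a folder/stack of en face images into paired (image, label) training
data for semantic segmentation: the FAZ is extracted per image in chunks
(with an optional per-chunk review hook), each extraction becomes a binary
label image (background 0, region 255), pairs are amplified by flips and
quarter-turn rotations applied identically to image and label, and finally
exported at training resolution via nearest-neighbour resize (labels must
stay strictly binary) plus cropping, together with a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .imaging_io import EnFaceImage, ImagingError, RegionMask, RoiPolygon, polygon_to_mask, write_image
from .ksm_core import ExtractionFailure, FazResult, KsmParams, extract_faz
from .preprocessing import BandpassParams

#: geometric amplification operators, applied identically to image and label
TRANSFORMS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "fliph": lambda a: a[:, ::-1],
    "flipv": lambda a: a[::-1, :],
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
}


@dataclass
class DatasetPair:
    """One training example: an image, its label, and how it was derived."""

    image: EnFaceImage
    label: RegionMask
    source: str = ""
    transform: str = "orig"

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ImagingError("image and label must share geometry")

    @property
    def provenance(self) -> str:
        return f"{self.source}__{self.transform}"


@dataclass
class StackResult:
    """Per-image results of a chunked stack extraction.

    ``results[i]`` is the FazResult for input i or None if that image failed;
    failures maps the input index to the error.
    """

    results: List[Optional[FazResult]]
    failures: Dict[int, ExtractionFailure]

    @property
    def n_ok(self) -> int:
        return sum(r is not None for r in self.results)


def process_stack(
    images: Sequence[EnFaceImage],
    chunk_size: int = 5,
    params: Optional[KsmParams] = None,
    bandpass: Optional[BandpassParams] = None,
    use_bandpass: bool = True,
    confirm_hook: Optional[Callable[[int, List[Optional[FazResult]]], None]] = None,
) -> StackResult:
    """Extract the FAZ from every image of a stack, in chunks of ``chunk_size``.

    Results keep input order; extraction failures are collected, not fatal.
    ``confirm_hook(chunk_index, chunk_results)`` is called after each chunk —
    the batch never blocks on it.
    """
    if len(images) == 0:
        raise ValueError("empty image stack")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    results: List[Optional[FazResult]] = []
    failures: Dict[int, ExtractionFailure] = {}
    for start in range(0, len(images), chunk_size):
        chunk = images[start:start + chunk_size]
        chunk_results: List[Optional[FazResult]] = []
        for offset, img in enumerate(chunk):
            try:
                chunk_results.append(extract_faz(img, params, bandpass, use_bandpass))
            except ExtractionFailure as exc:
                failures[start + offset] = exc
                chunk_results.append(None)
        if confirm_hook is not None:
            confirm_hook(start // chunk_size, chunk_results)
        results.extend(chunk_results)
    return StackResult(results=results, failures=failures)


def make_label_image(shape: Tuple[int, int], region) -> RegionMask:
    """Build a label raster: background exactly 0, the region exactly 255.

    ``region`` may be a RegionMask (geometry must match) or an RoiPolygon
    (rasterized into the given shape).
    """
    if isinstance(region, RoiPolygon):
        return polygon_to_mask(region, shape[0], shape[1])
    if isinstance(region, RegionMask):
        if region.shape != tuple(shape):
            raise ImagingError(f"label geometry {region.shape} != requested {tuple(shape)}")
        return region.with_pixels(region.pixels.copy())
    raise TypeError("region must be a RegionMask or RoiPolygon")


def amplify_dataset(
    pairs: Sequence[DatasetPair],
    ops: Sequence[str] = ("fliph", "flipv", "rot90"),
) -> List[DatasetPair]:
    """Amplify pairs by flips/rotations; output |pairs| x (1 + |ops|) examples.

    Every transform is applied identically to image and label.  Quarter-turn
    rotations require square rasters.
    """
    ops = list(ops)
    if not ops:
        raise ValueError("ops must be non-empty for amplification")
    unknown = set(ops) - set(TRANSFORMS)
    if unknown:
        raise ValueError(f"unknown transforms: {sorted(unknown)}")
    out: List[DatasetPair] = []
    for pair in pairs:
        h, w = pair.image.shape
        out.append(pair)
        for op in ops:
            if op in ("rot90", "rot270") and h != w:
                raise ImagingError(f"{op} requires a square image, got {h}x{w}")
            fn = TRANSFORMS[op]
            out.append(DatasetPair(
                image=pair.image.with_pixels(fn(pair.image.pixels).copy()),
                label=pair.label.with_pixels(fn(pair.label.pixels).copy()),
                source=pair.source,
                transform=op if pair.transform == "orig" else f"{pair.transform}+{op}",
            ))
    return out


def resize_nearest(arr: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resample to size x size (no interpolation: a binary
    label keeps its exact value set)."""
    h, w = arr.shape
    rows = np.minimum((np.arange(size) * h) // size, h - 1)
    cols = np.minimum((np.arange(size) * w) // size, w - 1)
    return arr[np.ix_(rows, cols)]


def crop_windows(size: int, crop_to: int, crop_mode: str) -> List[Tuple[str, int, int]]:
    """Top-left corners of the crop window(s): center crop or four tiles."""
    if crop_to > size:
        raise ValueError(f"crop_to={crop_to} exceeds the resized frame {size}")
    if crop_mode == "center":
        off = (size - crop_to) // 2
        return [("c", off, off)]
    if crop_mode == "fourtile":
        if 2 * crop_to > size:
            raise ValueError("fourtile needs crop_to <= resize_to / 2")
        e = size - crop_to
        return [("t0", 0, 0), ("t1", 0, e), ("t2", e, 0), ("t3", e, e)]
    raise ValueError(f"unknown crop_mode {crop_mode!r}")


def export_training_set(
    pairs: Sequence[DatasetPair],
    out_dir,
    resize_to: int = 512,
    crop_to: int = 256,
    crop_mode: str = "center",
) -> pd.DataFrame:
    """Write paired training files plus a manifest CSV.

    Each pair is nearest-neighbour resized to ``resize_to`` and cropped to
    ``crop_to`` per ``crop_mode``.  Files are named
    ``<source>__<transform>__{img,label}.png``; the manifest records source,
    transform, paths and label foreground pixel count.
    """
    if resize_to < crop_to:
        raise ValueError("resize_to must be >= crop_to")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = crop_windows(resize_to, crop_to, crop_mode)
    rows = []
    for pair in pairs:
        img_r = resize_nearest(pair.image.pixels, resize_to)
        lab_r = resize_nearest(pair.label.to_uint8(), resize_to)
        for tag, r0, c0 in windows:
            suffix = pair.transform if crop_mode == "center" else f"{pair.transform}_{tag}"
            img_crop = img_r[r0:r0 + crop_to, c0:c0 + crop_to]
            lab_crop = lab_r[r0:r0 + crop_to, c0:c0 + crop_to]
            img_path = out_dir / f"{pair.source}__{suffix}__img.png"
            lab_path = out_dir / f"{pair.source}__{suffix}__label.png"
            write_image(pair.image.with_pixels(img_crop), img_path)
            write_image(RegionMask(lab_crop, mm_per_pixel=pair.label.mm_per_pixel), lab_path)
            rows.append({
                "source": pair.source,
                "transform": suffix,
                "img_path": img_path.name,
                "label_path": lab_path.name,
                "faz_px": int((lab_crop > 0).sum()),
            })
    manifest = pd.DataFrame(rows, columns=["source", "transform", "img_path",
                                           "label_path", "faz_px"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
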