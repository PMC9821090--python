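"""Synthetic en face OCTA scene generator with known ground truth.

Produces images that emulate the features the extraction pipeline actually
depends on: a bright capillary network on a dark background, a central
avascular region of controlled shape and area, a rim of terminal capillaries
with optional signal dropouts, multiplicative (log-normal) speckle, and a
global high-brightness acquisition variant.  Vessels are procedural Bezier
strokes, not a hemodynamic model — the goal is a controlled test bed, not
biophysical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from skimage import measure
from scipy import ndimage

from .imaging_io import EnFaceImage, RegionMask, write_image

_BACKGROUND = 25.0  # avascular / stromal signal floor
_RING_INTENSITY = 170.0
_MARGIN = 8  # px the FAZ must keep from the frame edge


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic scene.

    size / mm_extent set the raster and physical scale (defaults mirror a
    3 mm scan exported at 1024 px).  faz_area_mm2 is the ground-truth
    avascular area; faz_irregularity in [0, 1) is the amplitude of the
    radial harmonic perturbation of the boundary; vessel_density in [0, 1]
    scales the number of strokes; gap_rate is the dropout probability of
    ~8 px capillary segments at the FAZ rim; noise_sigma is the log-normal
    speckle scale; brightness_shift and contrast_compress emulate
    high-brightness captures.  The seed fixes the full output.
    """

    size: int = 1024
    mm_extent: float = 3.0
    faz_area_mm2: float = 0.27
    faz_irregularity: float = 0.25
    vessel_density: float = 0.65
    gap_rate: float = 0.10
    noise_sigma: float = 0.12
    brightness_shift: float = 0.0
    contrast_compress: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 256:
            raise ValueError("size must be >= 256")
        if not 0.04 <= self.faz_area_mm2 <= 1.0:
            raise ValueError("faz_area_mm2 must lie in [0.04, 1.0]")
        if not 0 <= self.faz_irregularity < 1:
            raise ValueError("faz_irregularity must lie in [0, 1)")
        if not 0 <= self.vessel_density <= 1:
            raise ValueError("vessel_density must lie in [0, 1]")
        if not 0 <= self.gap_rate <= 1:
            raise ValueError("gap_rate must lie in [0, 1]")

    @property
    def mm_per_pixel(self) -> float:
        return self.mm_extent / self.size


#: acquisition variants: a typical capture, a globally bright capture with
#: stronger speckle and mild contrast compression, and a noisy low-quality one
PRESETS = {
    "default": {},
    "bright": {"brightness_shift": 60.0, "noise_sigma": 0.35, "contrast_compress": 0.15},
    "noisy": {"noise_sigma": 0.30, "gap_rate": 0.30},
}


def preset_spec(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Build a spec from a named acquisition preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticSpec(seed=seed, **kwargs)


@dataclass
class SyntheticScene:
    """A rendered scene: the image, its ground-truth FAZ, and provenance."""

    image: EnFaceImage
    truth_mask: RegionMask
    spec: SyntheticSpec
    vessel_mask: Optional[RegionMask] = None  # pixels where strokes were drawn


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def make_faz_shape(spec: SyntheticSpec) -> RegionMask:
    """Star-convex ground-truth FAZ mask hitting the target area within 2%.

    The boundary is a radial harmonic perturbation of a circle,
    r(theta) = s * (1 + sum_k a_k cos(k theta + phi_k)), with the scale s
    found by bisection on the pixel-count area.
    """
    rng = _rng(spec.seed, 101)
    n = spec.size
    target_px = spec.faz_area_mm2 / spec.mm_per_pixel ** 2

    # harmonic perturbation, normalized so max radial deviation = irregularity
    ks = np.arange(2, 7)
    amps = rng.uniform(0.3, 1.0, size=len(ks))
    if spec.faz_irregularity > 0:
        amps *= spec.faz_irregularity / amps.sum()
    else:
        amps *= 0.0
    phases = rng.uniform(0, 2 * np.pi, size=len(ks))

    c = (n - 1) / 2.0
    rows = np.arange(n, dtype=float)[:, None] - c
    cols = np.arange(n, dtype=float)[None, :] - c
    radius = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    base = 1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases))

    # feasibility: even the most perturbed radius must stay inside the frame
    s_max = (n / 2.0 - _MARGIN) / (1.0 + spec.faz_irregularity)
    ratio = radius / base  # pixel is inside iff ratio <= s

    lo, hi = 0.0, s_max
    if int(np.count_nonzero(ratio <= hi)) < target_px * 0.98:
        raise ValueError("target FAZ area unreachable at this raster size")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.count_nonzero(ratio <= mid) < target_px:
            lo = mid
        else:
            hi = mid
    mask = ratio <= hi
    area = int(mask.sum())
    if abs(area - target_px) / target_px > 0.02:
        raise ValueError("area calibration failed to converge within 2%")
    return RegionMask(mask, mm_per_pixel=spec.mm_per_pixel,
                      eye_id=f"synth{spec.seed}")


def _disk_offsets(r: float) -> np.ndarray:
    k = int(np.floor(r))
    dr, dc = np.mgrid[-k:k + 1, -k:k + 1]
    keep = dr * dr + dc * dc <= r * r
    return np.stack([dr[keep], dc[keep]], axis=1)


def _stamp(canvas: np.ndarray, vessel: np.ndarray, pts: np.ndarray,
           offsets: np.ndarray, value: float) -> None:
    """Paint disks of ``value`` at integer points ``pts`` onto the canvas."""
    if len(pts) == 0:
        return
    n = canvas.shape[0]
    coords = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    np.clip(coords, 0, n - 1, out=coords)
    canvas[coords[:, 0], coords[:, 1]] = value
    vessel[coords[:, 0], coords[:, 1]] = True


def _ring_points(truth: np.ndarray, gap_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Contour points of the FAZ rim with ~8 px segments dropped at gap_rate."""
    contour = max(measure.find_contours(np.pad(truth.astype(float), 1), 0.5),
                  key=len) - 1.0
    steps = np.hypot(*np.diff(contour, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    seg = (arc // 8.0).astype(int)  # ~8 px capillary segments
    keep = rng.uniform(size=seg.max() + 1) >= gap_rate
    pts = contour[keep[seg]]
    return np.round(pts).astype(int)


def _bezier(p0, p1, p2, npts) -> np.ndarray:
    t = np.linspace(0.0, 1.0, npts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def render_scene(spec: SyntheticSpec) -> SyntheticScene:
    """Render one synthetic scene (image + ground truth), fully seed-determined."""
    n = spec.size
    truth = make_faz_shape(spec)
    canvas = np.full((n, n), _BACKGROUND, dtype=np.float64)
    vessel = np.zeros((n, n), dtype=bool)

    # capillary rim hugging the FAZ boundary, with segment dropouts
    rng_gap = _rng(spec.seed, 202)
    ring_pts = _ring_points(truth.pixels, spec.gap_rate, rng_gap)
    _stamp(canvas, vessel, ring_pts, _disk_offsets(2.0), _RING_INTENSITY)

    # parenchymal vessels: random quadratic Bezier strokes avoiding the FAZ
    rng_v = _rng(spec.seed, 303)
    forbid = ndimage.binary_erosion(truth.pixels, np.ones((3, 3), bool),
                                    iterations=2, border_value=0)
    n_strokes = int(round(spec.vessel_density * 1000 * (n / 1024.0) ** 2))
    for _ in range(n_strokes):
        p0 = rng_v.uniform(0, n, size=2)
        ang = rng_v.uniform(0, 2 * np.pi)
        length = rng_v.uniform(0.08, 0.25) * n
        p2 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
        perp = np.array([np.cos(ang), -np.sin(ang)])
        p1 = 0.5 * (p0 + p2) + rng_v.uniform(-0.3, 0.3) * length * perp
        pts = np.round(_bezier(p0, p1, p2, max(int(1.5 * length), 2))).astype(int)
        pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < n)
                  & (pts[:, 1] >= 0) & (pts[:, 1] < n)]
        pts = pts[~forbid[pts[:, 0], pts[:, 1]]]
        radius = rng_v.uniform(1.2, 2.2)
        value = rng_v.uniform(120.0, 175.0)
        _stamp(canvas, vessel, pts, _disk_offsets(radius), value)

    # multiplicative log-normal speckle (mean-preserving), then global
    # brightness shift with mild contrast compression for bright captures
    rng_n = _rng(spec.seed, 404)
    if spec.noise_sigma > 0:
        z = rng_n.standard_normal((n, n))
        canvas *= np.exp(spec.noise_sigma * z - 0.5 * spec.noise_sigma ** 2)
    if spec.contrast_compress > 0:
        m = canvas.mean()
        canvas = m + (canvas - m) * (1.0 - spec.contrast_compress)
    canvas += spec.brightness_shift
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    image = EnFaceImage(pixels, mm_per_pixel=spec.mm_per_pixel,
                        eye_id=f"synth{spec.seed}")
    return SyntheticScene(
        image=image,
        truth_mask=truth,
        spec=spec,
        vessel_mask=RegionMask(vessel, mm_per_pixel=spec.mm_per_pixel,
                               eye_id=image.eye_id),
    )


def save_scene(scene: SyntheticScene, out_dir) -> dict:
    """Write image, truth mask and spec JSON for one scene; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = scene.image.eye_id or f"synth{scene.spec.seed}"
    img_path = write_image(scene.image, out_dir / f"{stem}__img.png")
    truth_path = write_image(scene.truth_mask, out_dir / f"{stem}__truth.png")
    spec_path = out_dir / f"{stem}__spec.json"
    spec_path.write_text(json.dumps(scene.spec.__dict__, indent=2))
    return {"image": str(img_path), "truth": str(truth_path), "spec": str(spec_path)}
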