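# Methods

## Extraction model and assumptions

The extraction pipeline assumes an en face OCTA projection of the
superficial retinal layer in which (i) perfused capillaries are bright and
the avascular zone dark, (ii) the FAZ is a single, roughly star-convex
region containing the image center, and (iii) failures of the vascular
signal appear as short interruptions of the capillary rim and as
signal-dependent speckle. Under those assumptions the FAZ is exactly the
central connected component of the complement of the *morphologically
closed* vessel mask: successive 3 × 3 dilations bridge rim interruptions
narrower than roughly twice the iteration count (in Chebyshev distance),
and matched erosions restore the boundary everywhere the rim was intact.
The method is deterministic: identical input and parameters give
byte-identical masks.

Erosion treats pixels outside the frame as vessel. This keeps the frame
edge from eroding into a spurious avascular ring and makes a fully
vascularized frame yield an empty avascular field, which is the correct
degenerate answer.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `filter_large` | 1024 | px | with the frame size as the large cutoff, the bandpass acts purely as a speckle smoother; structures the size of the frame (including the DC term) pass |
| `filter_small` | 3.5 | px | suppresses single-pixel/speckle scale while leaving ~10 px capillaries intact |
| `saturation_tolerance` | 5 | % | post-filter autoscale clips 2.5 % per tail before the linear 0–255 rescale |
| `n_dilate`, `n_erode` | 10 | iterations | bridges rim gaps up to ~20 px at 1024² scale; exposed because difficult material may need more or fewer passes. Fixed by the synthetic recovery suite (mean Jaccard ≥ 0.9 over seeded scenes) |
| `threshold_method` | isodata | — | the standard default auto-threshold of interactive image analysis; `otsu` selectable |
| `particle_min_px`, `particle_max_px` | 5000, 120000 | px @1024² | brackets physiologic FAZ areas (≈ 0.04–1.0 mm² at 3/1024 mm/px); rescaled by the pixel-count ratio when the raster differs from 1024² |
| `enlarge_px` | 4 | px | Euclidean growth compensating the half-width of the capillary rim |
| `center_policy` | nearest_center | — | among gate survivors: smallest centroid-to-center distance, ties broken by larger area, then lower label — a total order, hence reproducible |
| reference axial length | 24.2 | mm | magnification correction is `(AL/24.2)²`; the factor is reported separately so exact Littmann–Bennett coefficients can be substituted |

Notes on individual choices:

- **Enlarge semantics.** Region growth thresholds the Euclidean distance
  map (`distance ≤ enlarge_px`), not iterated 3 × 3 dilation, which would
  grow square (Chebyshev) rather than round neighbourhoods. Enlarging a
  single pixel by 4 gives exactly the 49-pixel digital disk of radius 4.
- **Hole filling** follows component selection so residual intra-FAZ noise
  specks cannot perforate the label. Background is flood-filled with
  4-connectivity, the dual of the 8-connected foreground.
- **Bandpass realization.** Gaussian low-pass times (1 − Gaussian) high-pass
  in the frequency domain on a mirror-padded power-of-two transform,
  cropped back after inversion. Mirror padding avoids wrap-around
  artifacts that would fabricate vessel signal at the frame border. When
  `filter_large` is at least the padded size, the high-pass factor is
  omitted entirely so the DC term passes. No claim of bit parity with any
  particular desktop implementation is made; the filter is specified (and
  tested) through band-energy behaviour: mid-band scales preserved within
  10 %, out-of-band scales strongly attenuated, translation equivariance in
  the interior.
- **Rasterization rule.** Polygons fill by the even-odd rule sampled at
  pixel centers; coordinates are 0-based `(row, col)` with centers on
  integers. ROIs serialize to a small JSON schema
  (`{"eye_id": ..., "vertices": [[r, c], ...]}`).
- **FN/FP normalization.** Both percentages are normalized by the union of
  the two regions. This makes `FN% + FP% = (1 − Jaccard) · 100` an exact
  identity, giving the excess/deficiency split a direct relationship to
  the similarity score.
- **Post-hoc after Friedman**: pairwise Wilcoxon signed-rank with
  Bonferroni adjustment (`p_adj = min(1, p·m)` over the m pairs). When a
  pairing has all-zero differences the Wilcoxon p is defined as 1.
- **16-bit inputs** are linearly min–max rescaled to 8 bits; multi-channel
  inputs collapse by ITU-R 601 luminance weights. Native inputs are
  expected to be 8-bit exports.

## Dataset factory

The annotation workflow processes stacks in chunks (default 5 images) with
an optional per-chunk review hook that never blocks batch runs. Labels are
written with background exactly 0 and region exactly 255. Amplification
applies flips and quarter-turn rotations identically to image and label;
export resizes by nearest neighbour (so label value sets survive exactly)
to 512² and crops to 256². The default crop is a single center crop, which
keeps the fovea; a `fourtile` mode (four non-overlapping 256² quadrants)
is selectable when more examples per eye are wanted. File names
(`<source>__<transform>__{img,label}.png`) plus the manifest CSV make every
pair self-describing. Typical U-Net training settings used with such
datasets (20 epochs, batch 12) are a downstream concern and are only noted
here; no training code ships with the package.

## Synthetic scenes: what they emulate, and what they do not

The generator emulates the features the pipeline is sensitive to: a bright
capillary network (procedural quadratic Bezier strokes, ~65 % density) on
a dark background, a capillary rim hugging the FAZ boundary with ~8 px
segment dropouts at `gap_rate`, a star-convex FAZ from radial harmonics
(k = 2…6) calibrated by bisection to the target area within 2 %,
mean-preserving multiplicative log-normal speckle (signal-dependent, as in
coherent imaging), and a high-brightness variant (additive shift 60, mild
contrast compression, stronger speckle) that reproduces the failure mode
the bandpass stage exists to fix. Default conditions: 1024² raster, 3 mm
extent, FAZ 0.27 mm², irregularity 0.25, gap rate 0.10, speckle σ 0.12.

Not emulated: hemodynamics and real plexus topology, projection artifacts,
motion/defocus, diseased-eye morphologies, and local (rather than global)
signal-strength loss. Passing the synthetic suite therefore demonstrates
the morphological logic, parameter plumbing and failure handling — not
clinical-grade accuracy on pathological scans.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the native 1024² raster
for recovery checks (20 seeded scenes; 8 for the bright-capture
comparison), at 512² for generator property sweeps, and at 32² against
brute-force per-pixel oracles for the morphology operators. The null
battery for the rank statistics uses 200 simulations of 40 blocks × 3
methods, matching a typical two-eyes-per-subject cohort of 20 volunteers;
its rejection rates are asserted within binomial tolerance of the nominal
5 % (the Friedman chi-square approximation is only asymptotic, so a small
finite-sample wobble around the nominal level is expected).

Degenerate inputs are defined, not left to chance: constant images cannot
be thresholded (extraction failure with stage provenance), autoscaling a
constant image is the identity, an empty size-gate census raises an
extraction failure carrying the full component census, and enlargement
clipped by the frame records a warning.

## Known limitations

- Iteration counts for dilation/erosion are calibrated on the synthetic
  suite, not transcribed from any particular interactive macro; on other
  devices or field sizes they should be re-tuned (they are plain
  parameters).
- The magnification correction is the squared axial-length ratio to a
  configurable reference; it is a first-order stand-in for full
  telecentricity-aware formulas.
- `mask_to_polygon` assumes a single component without holes and guarantees
  only Jaccard ≥ 0.99 round-trips for components of ≥ 100 px; sub-pixel
  boundary placement is not preserved.
- The comparison battery requires complete blocks (every method on every
  eye); there is no imputation for missing segmentations.
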