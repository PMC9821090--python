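# fazkit

Automatic extraction of the **foveal avascular zone (FAZ)** from en face
OCTA (optical coherence tomography angiography) images, plus everything
needed to turn those extractions into training data for semantic
segmentation and to grade segmentation agreement between methods.

The FAZ — the capillary-free region at the center of the macula — is a
clinical biomarker whose area and shape change in diabetic retinopathy,
vein occlusion, glaucoma and other disease. Tracing it by hand takes 50–100
boundary plots per image; `fazkit` automates the tracing with a classical
morphological pipeline and automates the *annotation* workflow around it,
so that large labeled datasets (image + binary label) can be produced with
minimal manual effort.

## The algorithm

Given an 8-bit en face image of the superficial retinal layer (nominally
1024 × 1024 px covering 3 mm × 3 mm):

1. **Bandpass denoise** — an FFT difference-of-Gaussians filter attenuates
   structures smaller than `filter_small` = 3.5 px (speckle) and larger than
   `filter_large` = 1024 px, followed by a contrast autoscale that saturates
   5 % of pixels. This stage rescues high-brightness captures.
2. **Binarize** the bright vasculature with a global isodata threshold.
3. **Close capillary gaps**: *n* = 10 successive 3 × 3 binary dilations
   bridge interruptions in the vascular signal.
4. **Recover the avascular field**: *n* matched erosions shrink the vessels
   back; the complement is the avascular region.
5. **Particle selection**: 8-connected components outside the size gate
   [5000, 120000] px (at 1024² scale; auto-rescaled for other rasters) are
   discarded, the component nearest the image center is kept, holes filled.
6. **Enlarge by 4 px** of Euclidean distance (distance-map thresholding) to
   compensate for the half-width of the capillary rim.

Agreement between two segmentations A (target) and B (result) is graded
with pixel counts:

    Jaccard(A,B) = |A ∩ B| / |A ∪ B|
    DSC(A,B)     = 2|A ∩ B| / (|A| + |B|)
    FN% = 100·|A \ B| / |A ∪ B|,   FP% = 100·|B \ A| / |A ∪ B|

so that `DSC = 2J/(1+J)` and `FN% + FP% = (1−J)·100` hold identically.
Areas are `pixels × (mm/px)²`, optionally corrected for ocular
magnification by the squared ratio of axial length to a 24.2 mm reference;
per-subject between-method coefficients of variation, Friedman tests with
Bonferroni-adjusted pairwise Wilcoxon post-hocs, and Spearman area
correlations round out the comparison battery.

A built-in synthetic OCTA generator renders scenes with a known
ground-truth FAZ (procedural Bezier vasculature, capillary rim with
dropouts, multiplicative speckle, high-brightness variants), so the whole
pipeline is testable end-to-end with no external data.

## Worked example

```python
from fazkit import SyntheticSpec, render_scene, extract_faz, jaccard, dsc

scene = render_scene(SyntheticSpec(seed=7))          # 1024², 3 mm, FAZ 0.27 mm²
result = extract_faz(scene.image)
print(f"FAZ: {result.pixel_count} px = {result.area_mm2:.4f} mm^2")
print(f"Jaccard vs truth: {jaccard(result.mask, scene.truth_mask):.3f}")
print(f"DSC vs truth:     {dsc(result.mask, scene.truth_mask):.3f}")
```

prints

```
FAZ: 32217 px = 0.2765 mm^2
Jaccard vs truth: 0.976
DSC vs truth:     0.988
```

i.e. the pipeline recovers the 0.27 mm² ground-truth avascular zone to
within ~2 % area and an "excellent" (≥ 0.9) Jaccard overlap.

The same flows are available from the shell:

```sh
fazkit synth   --n 20 --seed 1 --out scenes/ --preset default
fazkit extract --in scenes/synth1__img.png --out mask.png
fazkit dataset --in images/ --out train/ --chunk 5 \
               --amplify fliph,flipv,rot90 --resize 512 --crop 256
fazkit eval    --methods ksm:dir1 --methods manual1:dir2 --methods manual2:dir3 \
               --meta eyes.csv --out report/
```

`fazkit dataset` reproduces the annotation factory: chunked extraction
(5 images at a time), black/white label images (0/255), flip/rotation
amplification, nearest-neighbour 1024 → 512 resize and 256 crop, and a
manifest CSV pairing every exported image with its label.

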