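# Methods

`hcfm` implements an automated analysis pipeline for multi-channel 3D
confocal mosaics of environmental microbial eukaryotes (nano-plankton,
roughly 5–20 µm): object detection in overlapping fields of view,
extraction of a fixed 480-descriptor feature catalog per object, and
hierarchical random-forest classification. This note records the model,
its assumptions, the tunable parameters, and the choices made where the
procedure was genuinely open.

## Acquisition model

A sample is imaged as a rectangular mosaic of square fields of view.
Five channels are recorded per field: bright field plus four
fluorescence channels with distinct biological roles — DNA/nuclei,
intracellular membranes, cell surface, and chlorophyll autofluorescence.
Defaults (all overridable through `AcquisitionConfig`):

| parameter | default | units | meaning |
|---|---|---|---|
| `voxel_size_xy_um` | 0.188 | µm | lateral sampling |
| `voxel_size_z_um` | 1.090 | µm | axial step |
| `field_width_um` | 385.62 | µm | square field side |
| `frame_pixels` | 2048 | px | frame side |
| `overlap_fraction` | 0.10 | — | mosaic overlap in X and Y |

Arrays are indexed `(x, y, z)` with `x` fastest-varying in files; pixel
coordinates are 0-based and regions are half-open. Intensities stay as
stored integers up to thresholding (bit-exact thresholds); feature
computation promotes to floating point.

## Detection

1. **Background.** For each fluorescence channel, the mean and
   *population* standard deviation of all voxels of all fields of a
   sample are pooled before any per-field work (the distinction from the
   sample standard deviation is negligible at these voxel counts but is
   fixed here for reproducibility). The detection threshold is
   `max(mean + 1.5·std, 1)`. The mean-anchored rule is deliberately
   permissive: variance-partitioning thresholds such as Otsu's method
   under-detect when foreground occupies a small fraction of the image
   or when a channel contains no objects at all (Otsu then splits the
   background mode itself). The bright-field channel is never
   thresholded; it contributes features only.
2. **Almost-max projection.** Each Z-column reduces to its
   *second-highest* value. This suppresses single-voxel spikes (detector
   shot events) at the cost of suppressing any structure that intersects
   only one Z-plane — at the 1.09 µm axial step this sets an effective
   minimum object thickness of about two planes.
3. **Masking.** The projection is median filtered (3×3, reflected
   edges — the smallest standard window, preserving ~5 µm structures)
   and thresholded strictly (`>`). Channel masks are OR-combined, then
   opened and closed with the 4-connected cross structuring element (one
   iteration each), then background regions not connected to the image
   border are filled (4-connectivity). Erosions treat out-of-bounds as
   foreground so border-touching objects are not shaved off the border
   before the border filter can see them.
4. **Filtering.** 4-connected labeling; objects with projected area
   strictly below **12.6 µm²** are removed, as are objects with any
   pixel on the four image borders. (The 12.6 µm² figure is adopted
   verbatim as the published cutoff; note it does not equal the area of
   a 5 µm-diameter circle, ~19.6 µm².)

## Mosaic deduplication

Fields overlap by 10 %, so one cell can be detected in up to four
fields. Each object is owned by the unique *canonical field* whose core
region contains its global centroid; cores are field rectangles shrunk
by half the overlap width on every edge shared with a neighbor, so cores
tile the mosaic exactly. Mosaic-boundary fields extend their cores to
the mosaic edge. A centroid exactly on a core boundary belongs to the
field with the smaller (row, col) in row-major order; cores are
implemented as open-left/closed-right intervals (closed at the left
mosaic edge), which realizes that tie-break deterministically in
floating point. Detections outside their canonical field are discarded;
survivors are renumbered 1..K on the (row, col, label) sort key, so the
registry is independent of field processing order.

**Known limitation:** an object larger than the overlap width that is
truncated in *every* field touches a border everywhere and is removed
everywhere — such objects are systematically missed, by construction of
the geometry-only rule (no cross-field image registration is attempted).

## Sub-objects and the 480-descriptor catalog

Per object, each fluorescence-channel crop (bounding box, masked to the
object footprint) is median filtered in 3D (3×3×3, reflected edges) and
thresholded at the channel's *global* threshold; 6-connected components
smaller than **0.5 µm³** are removed. Reusing the global threshold
(rather than re-estimating on the crop) is a deliberate reading of "the
same thresholding procedure": crops are mostly foreground, so local
re-estimation would be badly biased. This choice is flagged here because
the alternative is defensible.

The catalog (version `hcfm-480-v1`) has exactly 480 entries:

| block | count | scope |
|---|---|---|
| Haralick 13 statistics, mean + range over 4 directions | 26 × 5 channels | per channel |
| uniform LBP histograms (r=1/8 pts → 10 bins, r=2/12 pts → 14 bins) | 24 × 5 | per channel |
| Zernike magnitudes to degree 8 | 25 × 5 | per channel |
| intensity statistics (min, max, mean, std, median, MAD, skewness, kurtosis, integrated, fraction-above-threshold) | 10 × 5 | per channel |
| 2D morphology of the combined mask | 20 | combined |
| 3D biovolume/sub-object statistics | 5 × 4 | fluorescence channels |
| pairwise 3D overlap (Jaccard, smaller-fraction) | 2 × 6 pairs | channel pairs |
| 3D bounding-box extents (x, y, z) | 3 | combined |

Numerical conventions, fixed for reproducibility:

- Haralick co-occurrence at distance 1 in 4 directions, accumulated only
  over pixel pairs both inside the mask, after quantization to 64 gray
  levels spanning the object's min–max.
- Zernike moments on the disk circumscribing the mask (center = mask
  centroid, radius = half the larger bounding-box side), computed on the
  masked intensity normalized to unit total — magnitudes are therefore
  rotation-invariant and invariant to positive intensity scaling.
- `biovolume_um3` counts *all* above-threshold voxels after 3D median
  filtering; `subobject_total_volume_um3` sums the retained (≥ 0.5 µm³)
  components. The two differ by the small-component mass, which is why
  both exist as separate catalog entries.
- `fraction_above_threshold` is 0 for the bright-field channel, which
  has no threshold.
- Degenerate cases (empty masks, constant intensity, < 2 co-occurring
  pixels) produce 0, never NaN — classifiers require finite inputs.

All 480 descriptors are computed in crop-relative coordinates and are
therefore invariant to whole-voxel translation.

## Classification

Categories form a fixed 4-level hierarchy (coarse groups → finest
taxo-morphological categories). Training-set curation keeps categories
with **strictly more than 30** specimens and does not reweight classes.
The classifier is a random forest with **500 trees**, √480 ≈ 22 feature
candidates per split, unlimited depth, bootstrap sampling, deterministic
per seed. Predictions carry a confidence score: the difference between
the highest and second-highest class probabilities (second-highest
defined as 0 for a single-class model); probability ties break to the
lower class index. Leaf predictions are aggregated to every ancestor
level for per-level accuracy, per-category recall, and confusion
matrices. Accuracy is estimated by stratified 10-fold cross-validation
(the estimation protocol was an open choice; CV is consistent with how
the feature-reduction analysis is defined). Feature importances are
impurity-based (Gini), normalized by their mean so 1 marks average
importance; in the feature-reduction curve, importances are recomputed
inside each CV fold on the training portion only, and the selected
index set is sorted so that k = 480 reproduces the plain CV run exactly.

## Abundance and covariate correlation

Counts are normalized to concentrations per liter of seawater; counts
and volumes of technical replicates are summed *before* division (not
averaged after). Covariate relationships use Spearman rank correlation
over the samples containing the taxon — samples with a zero count are
excluded, which leaves rho and n unchanged when such samples are added.
Ties take average ranks; p-values are exact (full permutation
enumeration) for n ≤ 9 and use the large-sample approximation otherwise;
a least-squares line is reported for display only. A "live cell"
predicate (preserved organellar content) is operationalized as: at least
one DNA sub-object *and* non-zero membrane biovolume. This is this
package's concrete reading of an otherwise qualitative criterion.

## Synthetic scenes

The generator renders ground-truthed mosaics under the acquisition
geometry above: six cell archetypes (surface-shelled sphere, chain of
overlapping ellipsoidal cells, spiked core, torus, speckle-textured
blob, touching sphere pair) as analytic solids sampled on the
anisotropic voxel grid, with channel-specific structure (one nucleus per
cell, membrane fill, surface rim, 0–4 chloroplasts, darker bright-field
shadow) over Gaussian background noise, optionally contaminated with
rare hot-voxel spikes (a heavy-tailed component that the almost-max
projection is designed to reject). All per-object randomness is frozen
when the scene spec is built, so an object straddling a field boundary
renders consistently in every field imaging it. Archetype sizes are
drawn so every rendered object is safely above both detection limits
(≥ two z-planes thick at any axial phase; projected area comfortably
above 12.6 µm²) — cells at those limits would be legitimately and
erratically lost, which is a property of the method, not of the
generator.

What the generator does *not* emulate: optical blur (the pipeline does
no deconvolution, so a point-spread function would add realism without
exercising any code path), spectral bleed-through, staining variability,
debris, and out-of-focus structure. Passing tests therefore demonstrate
the pipeline's contracts and geometry, not field performance on real
seawater samples.

Packaged fixtures (all generated at run time, nothing stored):

- `dim_field` — one 512-px field, 30 low-contrast particles visible only
  in the membrane channel over spike-contaminated noise. Constructed so
  the mean+1.5σ detector separates particles from background while the
  per-channel Otsu variant fails: on the object-free fluorescence
  channels Otsu bisects the unimodal background, flooding the OR-combined
  mask and swallowing the particles into border-touching components.
- `six_classes` — 150 objects per archetype over 100 single fields of
  256 px (the bright-field appearance of the shelled sphere and the
  textured blob is identical by construction, so bright-field-only
  features cannot reach full-catalog accuracy).
- `mosaic_straddle` — a 3×3 mosaic of 512-px fields with 10 objects
  deliberately placed inside inter-field overlap slabs (offset ~0.7 µm
  from the core midline so detection noise cannot flip their canonical
  side) plus 12 interior objects.

Fixtures use 256–512 px frames instead of the full 2048 px: the voxel
size, overlap fraction, and all thresholds are unchanged, and the frame
side enters the pipeline only through mosaic geometry, which the
straddle fixture exercises directly.

## Known numerical limitations

- **Axial discretization.** At the 1.09 µm z-step, the 3×3×3 median
  filter erodes small sub-objects substantially: measured DNA-nucleus
  biovolume is ~6 % low at r = 2.5 µm, ~9 % low at r = 2.0 µm, ~18 % low
  at r = 1.5 µm, and worse below (a 1 µm-radius sphere spans barely two
  planes). Sub-object volumes within 15 % of truth can only be expected
  for radii ≳ 2 µm.
- **Thin structures.** Anything intersecting a single Z-plane (spine
  tips, thin frustules lying flat) vanishes from the almost-max
  projection by design.
- **Border bias.** The border filter plus geometry-only deduplication
  systematically misses objects wider than the mosaic overlap that are
  truncated in every field (see above).
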