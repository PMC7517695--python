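# Methods

`echowall` measures the left-ventricular posterior wall thickness (LVPWT)
on a single grayscale echocardiographic frame as

    LVPWT = k · d        [mm]

where `d` is the pixel distance between the wall's upper and lower edge
contours and `k` is the normalized scale in mm per pixel, recovered from
the on-screen ruler. This note documents the model behind each stage, the
parameters that matter, the numerical conventions, and the limits of what
the synthetic phantoms can show.

## Pipeline

1. **Localization.** A 200×200 window slides over the frame at a 25 px
   step. Windows whose mean gray falls strictly below a threshold
   (typically 50; 70 for brighter acquisitions) are discarded without
   prediction — they are non-anatomical background. Survivors are resized
   to 208×208 (bilinear) and scored by a small CNN; the window with the
   highest target-class probability wins, ties going to the smallest
   (row, col).
2. **Enhancement.** The located region is denoised with non-local means
   (NLM) and then smoothed with a grayscale morphological opening (3×3
   square element), which removes isolated bright glitches and thin
   bridges while preserving the wall's shape.
3. **Contour extraction.** Two-stage threshold segmentation: a prior gray
   range picks the wall's intensity band and the largest 8-connected
   component; Otsu's inter-class-variance criterion then re-estimates the
   threshold inside a sampling window centered on each initially
   segmented edge (one adjustment per edge), clamped back into the prior
   range. The upper/lower contours are the per-column minimum/maximum
   rows of the re-segmented component — continuous by construction.
4. **Quantification.** Measurement points are the intersections of the
   lower contour with 45° lines `r + c = b`, b = 140, 145, …, 185 in
   window-local coordinates. Each point's Euclidean distance to the
   nearest upper-contour pixel enters the reference distance group; after
   dropping one maximum and one minimum, the mean is `d`. The ruler is
   detected by low-gray binarization plus length/area screening of the
   connected segments; the median gap between consecutive tick centers is
   `l` (pixels per scale unit), and `k = unit_mm / l` with `unit_mm` =
   10 mm per ruler interval.

## The window classifier

A 7-layer network: C1 (3×3 conv, stride 1, 16 channels) → P1 (3×3 max
pool, stride 2) → C2 (3×3 conv, stride 1, 16 channels) → P2 (3×3 max
pool, stride 1) → FC1 (128) → FC2 (128) → 2-way softmax, all valid (no
padding), ReLU activations, dropout p = 0.5 after FC1 and FC2 during
training. On a 208×208 input the spatial sides are 208 → 206 → 102 → 100
→ 98. Note the 102: 3×3 stride-2 valid pooling of a 206-side map yields
⌊(206−3)/2⌋+1 = 102, and FC1's input is sized accordingly (98·98·16).
Published descriptions of this architecture sometimes quote 112/110/108
for the pooled chain, which is not consistent with a 3×3 stride-2 valid
pooling; we follow the kernel/stride arithmetic.

Choices the architecture description leaves open, fixed here:

* **Pooling type**: max (mean selectable only by code change; max is the
  convention for detection-style nets).
* **Loss / optimizer**: softmax cross-entropy, plain SGD (momentum
  optional via `TrainConfig.momentum`), gradients averaged over the
  batch. Training settings: 5000 iterations, batch 20, learning rate
  1e−4 at full scale; the test suite and acceptance study use 200
  iterations, which already separates phantom patches perfectly.
* **Initialization**: He-normal, seeded; biases zero.
* **Input scaling**: intensities are mapped to [−0.5, 0.5]
  (`x/255 − 0.5`). Zero-centering keeps about half of the randomly
  initialized rectifier units active on both bright and dark windows;
  with nonnegative inputs a network this narrow can start with every
  unit dead on bright patches and never learn.
* **Patch resize** 200→208: bilinear.

The network, including backpropagation, is implemented directly on numpy
(im2col convolutions, strided-view max pooling, BLAS matmuls); the sizes
involved make this entirely adequate on one CPU core (~2 s per training
iteration at batch 20).

## Non-local means

The output at pixel i is Σ_j w(i,j)·v(j) over the 21×21 search window,
with w(i,j) ∝ exp(−‖P(i)−P(j)‖²_a / h²) normalized so Σ_j w(i,j) = 1.
‖·‖²_a is the Gaussian-weighted mean of squared differences between the
two 7×7 patches; the Gaussian kernel (std `a`, default 1.5 px) is
normalized to sum 1, and `a = inf` selects uniform patch weighting. The
center pixel's pre-normalization weight follows the formula literally
(distance 0 → weight 1); borders are reflection-padded; the result is
rounded half-up back to 8 bits.

The published filtering intensity h = 8 is retained. Note its scale
dependence: on a wall at gray ~200 with 20% multiplicative speckle, the
pixel standard deviation is ~40, so patch distances dwarf h² and NLM is
close to an identity there — the morphological opening and the robust
distance statistics then carry the speckle suppression. On low-amplitude
noise (or pre-compressed clinical video frames) NLM contributes real
smoothing. This is a property of the published parameterization, not of
the implementation.

## Otsu refinement

`otsu_threshold` evaluates the inter-class variance
g(T) = ω₀ω₁(μ₀−μ₁)² at all 256 levels (class 0: intensity ≤ T) and
returns the smallest maximizer; the returned statistics satisfy
μ = ω₀μ₀ + ω₁μ₁ and the algebraic identity between the two variance
forms to 1e−9. "Adjusted twice" is read as one Otsu adjustment per edge
(upper, lower); a sequential two-pass variant per edge is available via
`passes=2`. A degenerate (constant) sampling window keeps the prior
lower bound; out-of-range Otsu values are clamped to the nearest prior
bound. The sampling window side defaults to 31 px (unstated in the
source description; large enough to contain both modes, small enough to
stay local).

**Prior range calibration.** The prior gray bounds are not published;
they are configuration. The shipped default [100, 255] comes from
phantom calibration: after opening, the speckled sector background
(gray 60, σ = 0.2) stays below ~75 while the wall (gray 200) stays above
~110, and 100 splits the gap. Clinical frames need their own prior
analysis; the default is explicitly not a published value.

## Scale and distance conventions

* **Scale normalization**: the printed form k = l/d × 10 would cancel d
  in LVPWT = k·d, making the thickness independent of the wall; we use
  the dimensionally consistent k = unit_mm / l (mm per pixel) with
  unit_mm = 10 mm — the same "×10" factor attached to the unit length.
* **Ruler detection**: after length/area screening, surviving segments
  are grouped by centroid column and the largest vertically aligned
  group is taken as the ruler — stray bright fragments elsewhere in the
  frame do not form a tall aligned stack. `l` is the median of
  consecutive center gaps, robust to a missing or spurious tick.
* **Pixel-span correction**: the distance between the *centers* of the
  two edge pixels of a wall spanning t pixel rows is t − 1. The pipeline
  adds `edge_correction_px` = 1.0 (half a pixel per boundary) so the
  reported d is the full spanned extent — the quantity a caliper placed
  on the outer edges reads and the quantity the phantom ground truth
  counts. On noiseless phantoms this makes the measurement exact rather
  than one quantization unit short.
* **45° line convention**: lines r + c = b with row down / column right;
  the mirrored family r − c = b is selectable
  (`PointSelectionParams.orientation="diff"`). A selected point is kept
  only if some contour pixel in its 2×2 block lies exactly on its line
  (the "diagonal-only" neighborhoods, where the line threads between
  pixels, are filtered).
* **Degenerate distance groups**: with one or two distances the plain
  mean is used; an empty group is an error.
* **Hypertrophy call**: strict inequality against `cutoff_mm`. No
  numeric cutoff is published with the method; the shipped 11 mm default
  is an external clinical convention and must be reviewed per site.

## The phantom generator

Phantoms emulate exactly the features the pipeline consumes: a dark
frame (gray 5) with a brighter circular sector (apex near top-center,
half-angle 35°, fill gray 60); a horizontal wall band (gray 200, default
20 px thick, 260 px wide, optional tilt) in the sector's far field;
mean-one multiplicative Gaussian speckle (`pixel × (1 + σ·N(0,1))`,
clipped to 8 bits, default σ = 0.2); and a ruler overlay of 1×3 px ticks
at 255 every `ruler_pitch_px` rows, drawn after speckling, as device
graphics are. All randomness flows through one seeded generator per
call, so identical parameters and seed give bit-identical images.

What the phantom does **not** emulate — and what passing tests therefore
do not show about clinical data: spatially correlated speckle (real
resolution cells span several pixels; the phantom's noise is i.i.d. per
pixel, which is harsher at the single-pixel scale), point-spread blur of
the wall edges (phantom edges are crisp), anatomical context
(papillary muscles, trabeculae, chordae near the posterior wall),
cardiac-phase selection from video, and scan-conversion artifacts.
Parameter-recovery results on phantoms validate the pipeline's
geometry, calibration, and robustness logic, not its clinical accuracy.

Training patches are 200×200 crops resized to 208×208: positives
centered on the band with ±10 px jitter (so the classifier's score peaks
when the wall is centered, which is what makes the argmax window land on
the wall), negatives rejection-sampled to avoid the band entirely.

## Problem sizes in the shipped studies

The acceptance study and test suite train on 60 patches (30 per class)
for 200 iterations and evaluate on 20 speckled phantoms (wall thickness
12–30 px, scale 0.30–0.59 mm/px, σ = 0.2) plus 3 noiseless phantoms —
sizes chosen so the full study runs in minutes on one core while still
exercising every stage at realistic geometry. At these sizes the
end-to-end relative error is typically ≤ ~13% worst-case with a median
of a few percent, the scale is recovered exactly, and noiseless phantoms
are measured exactly.

## Known limitations

* The NLM intensity h = 8 is fixed to the published value and is weak
  against high-amplitude speckle (see above).
* The min-distance statistic is sensitive to downward spikes in the
  upper contour: a single deep notch shortens the distances of every
  nearby measurement point, and the trim removes only one extremum.
* Localization assumes exactly one target region; multi-window
  aggregation is out of scope.
* Only still frames are handled (no DICOM or video; no systole/diastole
  phase selection), and only the posterior wall (no septum).
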