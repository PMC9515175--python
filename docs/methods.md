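# Methods

This note documents the measurement model implemented by `colonymorph`,
the parameters that matter, the synthetic forward model used for
validation, and the numerical and design choices made where the problem
was genuinely open.

## Measurement model

### Image normalization

Images are loaded as float64 intensities in [0, 1]: integer samples are
divided by `2^bitdepth − 1` (255 or 65535). Multi-channel input collapses
to one channel either by explicit channel selection or by the BT.601
luminance weights (0.299, 0.587, 0.114); fluorescence data is normally
single-channel so the weights rarely matter, but they are fixed and
documented so conversions are reproducible. Pixel calibration (µm/pixel)
is supplied by the user per image set; areas are reported as
`pixels × (µm/pixel)²`.

### Segmentation

The chain is grayscale erosion → Otsu threshold → binarization → contour
extraction:

* **Erosion** is a k×k windowed minimum (default k = 5, edge-replicated
  borders). It suppresses isolated bright speckle before thresholding.
  Because a windowed minimum also moves every step edge inward by
  (k−1)/2 px — a systematic negative area bias of ~4% on a 100 px radius
  colony — the thresholded mask is dilated with the same window before
  contour extraction. For step edges the erode–threshold–dilate
  combination acts as a binary opening: speckle smaller than the window
  stays removed, boundary position is restored.
* **Otsu's threshold** maximizes the between-class variance
  `ω₀ω₁(μ₁−μ₀)²` over a fixed 256-bin histogram of [0, 1], regardless of
  input bit depth; ties take the lowest candidate boundary. Constant
  images raise a degenerate-input error.
* **Contours** are extracted by border following on the 0.5 iso-level of
  the zero-padded mask (so regions touching the frame still close), with
  outer and hole boundaries both reported, and sorted by descending
  shoelace area; ties break by top-most then left-most vertex.

The largest contour is the periphery. For the core, the second-ranked
contour is accepted when it lies inside the periphery and its area is
between 1% and 90% of the periphery area (both gates configurable) —
this covers images where the core manifests as an interior boundary of
the global mask. When the global threshold separates only colony from
background (a single filled blob, as for a clean two-level colony), a
second Otsu pass restricted to pixels inside the periphery recovers the
core as the bright inner region. The second pass is additionally gated on
a minimum contrast between its two intensity classes (default 0.10):
a texture-free colony's interior split would separate noise quantiles
whose class means differ by only ~2 noise SDs, well under the gate, so
such colonies correctly report "core absent". The gates are deliberately
conservative; they reject dust and plate-edge artifacts at the cost of
missing very faint cores.

### Deformation ratios

The separating line passes through the layout's seeding point,
perpendicular to the unit vector **u** from seeding point to source;
"exposed" is the half-plane containing the source. Controls default to
the image-vertical line with **u** pointing right, purely to fix a
geometry; their ratios are interpreted through the augmentation scheme
instead. The seeding point, not the fitted ellipse center, anchors the
split (a `center_mode="centroid"` fallback uses the periphery centroid
when no coordinates were recorded).

Each half-contour (vertices partitioned by signed distance, with the two
line crossings interpolated so both ends lie on the line; if edge wiggles
produce more than two crossings, the longest arc per side is used) is
mirrored across the line and fitted with the direct least-squares
algebraic ellipse fit (Halir–Flusser, as implemented by
scikit-image's `EllipseModel`). Ratios compare the two fitted ellipses'
half-extents along **u** (horizontal) and **u**⊥ (vertical), using the
ellipse support function `√(a²cos²α + b²sin²α)` rather than raw
semi-axes, because fitted ellipses need not be axis-aligned. The
numerator is the unexposed half, so inhibition reads > 1. An alternative
would be to compare semi-axes directly; for near-axis-aligned fits the
two agree, and the projected-extent form is the one that generalizes to
off-axis sources.

### Intensity analysis

"Periphery" here means the annulus periphery ∖ core, so the two regions
are disjoint. Ratios are exposed-half mean over unexposed-half mean;
pixels exactly on the separating line belong to neither half. Controls
average three partition ratios about the seeding point — left/right,
top/bottom, and (upper-left + bottom-right) vs (upper-right +
bottom-left) quadrants — with an arithmetic mean (the partitions'
ratios are all near 1 for controls, so the choice of mean is
inconsequential; arithmetic is the simplest).

The leading-edge band is built from the Euclidean distance transform of
the rasterized periphery: interior pixels within `width` (default 20) of
the boundary, intersected with the exposed half. A distance transform is
simpler and better-behaved than polygon offsetting at this scale. The
regression is ordinary least squares of band intensity on pixel distance
to the source (distances in pixels by default); constant intensity
returns slope 0 with R² = 0 by convention, and a band whose pixels all
sit at one distance raises a rank-deficiency error.

### Group statistics

Two-sided pooled-variance Student's t-tests per (metric, day, group)
against the control group, significance at p < 0.05, unbalanced group
sizes allowed, **no multiple-testing correction** — each comparison cell
is reported raw, so table-wide error rates are not family-wise
controlled. A Welch variant is available behind a flag. Tests are
unpaired across days: day-wise comparisons are treated as independent
samples even when the same plates were imaged daily, which is
conservative about structure the layout file does not record. Degenerate
zero-variance samples with equal means return p = 1.

## Synthetic forward model

The generator emulates the phenomenology the pipeline measures, not
biofilm growth physics:

* **Footprint**: two half-ellipses sharing the vertical axis through the
  seeding point — unexposed horizontal semi-axis `r_u` (default 100 px),
  exposed `r_e = f·r_u`, vertical `r_v` (default 90 px). The horizontal
  deformation ratio of this family is exactly `r_u/r_e = 1/f`, which is
  why it was chosen. Crescent (concave) shapes are not representable.
* **Core**: a scaled copy (`core_scale`, default 0.4) of the *unexposed*
  semi-axis on both sides, hence symmetric by default regardless of
  periphery asymmetry; `core_asymmetry` deforms it when needed.
* **Intensity**: flat levels per region (background 0.08, periphery
  0.45, core 0.85) plus, over colony pixels, a gradient `g·(d − d̄)`
  linear in the distance `d` to the virtual source (mean-centered so the
  levels keep their meaning), plus i.i.d. Gaussian noise (default
  sd 0.02). Levels must satisfy mean ± 3 sd ∈ [0, 1] so clipping stays
  a tail event.
* **Calibration**: 50 µm/pixel, so nominal source distances of 1/1.5/2 cm
  put the virtual source 200/300/400 px right of the seeding point.
* **Cohorts**: the default cohort mirrors a one-sided-exposure study
  design — group sizes 12/11/9/12 for 1 cm/1.5 cm/2 cm/control, one image
  per plate per requested day (default day 3; days 1 and 2 scale all
  radii by 0.5 and 0.75). Effect sizes fall off with distance: asymmetry
  factors 0.70/0.90/0.97 and gradients 5·10⁻⁴/1.5·10⁻⁴/5·10⁻⁵ intensity
  per px, the near-source gradient ten times the far-source one. Plate
  individuality is multiplicative `1 + N(0, 0.03)` jitter on each
  semi-axis, fixed per plate across days; per-plate random streams derive
  from `(master_seed, group index, plate index)` so any subset is
  reproducible in isolation.

**What passing on synthetic data does and does not show.** The generator
produces sharp two-level region boundaries, spatially white noise, and
elliptical geometry. Real macrocolonies have soft edges, wrinkled core
texture, vignetting and background structure; segmentation accuracy and
core-detection gates validated here therefore bound behavior on clean
images only, and the erosion-compensation argument (step edges) holds
only approximately for diffuse edges. The statistical layer, oracle
equivalences (Otsu, OLS, t-test) and all geometric invariants
(symmetry nulls, rotation invariance, mirror reciprocity) are
data-distribution-free and transfer directly.

## Numerical choices and degenerate inputs

* Coordinates are (row, col), 0-based, origin top-left, everywhere.
* Otsu returns a bin *edge*; masks use strict `intensity > threshold`.
* Shoelace area of the extracted sub-pixel contour is used as the
  contour's enclosed area; it tracks the rasterized pixel count to ~1–2%
  for colony-scale regions (asserted in tests).
* Ellipse fits require ≥ 5 distinct vertices; collinear input fails.
  Fitted `a < b` outputs are normalized by swapping axes and rotating θ
  by π/2 into [0, π).
* Validation sizes were chosen to keep the full suite in a few minutes on
  one CPU: cohort-replication runs use a 256² grid with 64 px colonies
  (50 replicates × 20 plates), single-colony checks the default 360² grid.
* Results CSVs print floats at 17 significant digits, making
  write→read→write cycles and rerun comparisons byte-stable.

## Known limitations

* One colony per image; no multi-colony scene splitting.
* No background subtraction, flat-field correction, or calibration of
  fluorescence intensity to viability — intensity is treated as a proxy.
* Crescent-shaped colonies (source closer than ~1 cm) and agar-substrate
  effects are out of scope: no concavity metric is defined.
* ND2 reading requires an optional third-party reader at runtime; the
  portable contract is PNG/TIFF.
* The leading-edge regression is fit per colony; pooling pixels across
  colonies of a group is left to downstream analysis of the scatter CSVs.
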