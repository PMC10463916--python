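# Methods

`sidermap` quantifies the spatial relationship between chronic cortical
iron deposits (cortical superficial siderosis, cSS) and local
neuroinflammatory cells — GFAP-positive reactive astrocytes and
CD68-positive activated microglia/macrophages — from object detections
on serial histopathological sections.  The inputs are per-section
tables of detected object coordinates (μm) plus binary cortex masks;
everything downstream of cell detection is covered here.

## Coordinate conventions

All coordinates are μm with the origin at the top-left corner of the
section's mask raster, x rightward and y downward.  Grids are half-open
(`[i·s, (i+1)·s)`) with 0-based indices, so a point exactly on an
interior cell edge belongs to the cell to its right/below.

## Co-registration with count conservation

Adjacent GFAP and CD68 sections are mapped onto their iron section by
an affine transform followed by a free-form B-spline deformation, both
estimated on Gaussian-smoothed binary cortex masks with a mean-squares
objective (SimpleITK).  Registration quality is the Dice overlap of the
masks after warping; sections below a configurable threshold (default
0.90) are flagged as co-registration failures and recorded in the
exclusion log, so that sections-in = sections-analyzed +
sections-excluded at every stage.

A binary mask constrains a deformation only at its boundary.  An
aggressively optimized free-form stage therefore invents interior
displacement the data cannot support — on ribbon-shaped masks it can
make warped maps *less* faithful than no registration at all.  The
non-rigid stage is consequently coarse (4×3 control mesh) and
early-stopped (10 L-BFGS-B iterations) by default; both knobs are
exposed.

Object count matrices are warped by linear resampling of the
rasterized mass followed by a single global rescale
`total_before / total_after`, so the warped section carries exactly the
same number of objects as the source (relative error ≤ 1e−9 by
construction).  Linear resampling is not mass-preserving under a
non-rigid map; the global factor absorbs the net loss, while local
Jacobian effects remain — acceptable because downstream analyses bin to
500 μm pixels, an order of magnitude above the residual registration
error.

## Depth, artificial layers, edge/inner split

The pial boundary is the set of in-cortex cells 4-adjacent to
background; interior holes count as pial (leptomeninges line sulci),
and raster-edge cells with no background neighbour inside the image do
not — masks should therefore touch the raster edge on their deep
(white-matter) side.  Depth is the Euclidean distance (μm) to the
nearest boundary cell (a geodesic mode exists behind a flag; it matters
only for strongly folded masks).  Artificial layers are 1000 μm depth
bands; only the first five are analyzed, matching the 1–4.5 mm range of
human cortical thickness.  The edge/inner reanalysis splits the cortex
at 1000 μm depth; edge heat maps use 250 μm pixels.

## Heat maps and iron burden categories

The cortex bounding box is tiled with square pixels (500 μm default),
anchored at the bounding-box corner (grid phase configurable in whole
mask cells).  A pixel is valid when at least one third of its area is
in-cortex, i.e. pixels with more than two thirds of their area outside
the cortex are excluded; counts are kept for every pixel so totals are
conserved.  Iron burden per pixel is categorized as very low (0–5
objects), low (6–15), medium (16–25), high (26+); real-valued warped
counts are rounded half-up before categorization, because the
categories are defined on object counts.  At 250 μm the same integer
boundaries are used by default, with an area-scaled alternative
(boundaries × 1/4) behind a flag.

Category profiles average marker counts per pixel within each iron
category, per brain (or per section for the small macrohemorrhage
group); a category with no pixels in a brain is *missing*, not zero,
which is what the incomplete-block rank test downstream consumes.

Limitation worth knowing: comparing raw counts per pixel across iron
categories carries a tissue-area confound at the cortical edge —
partial pixels hold less tissue and so fewer counts of *everything*,
and edge pixels also differ systematically in iron.  With a strongly
surface-concentrated iron process this can by itself tilt a
category profile.  The null-calibration check below therefore uses
full-pixel geometry; on real data the edge/inner reanalysis bounds the
artifact.

## Ring-coefficient model

For each pixel of the iron heat map, ring k (k = 1..3) is the set of
valid pixels at Chebyshev lattice distance k (8/16/24 pixels on an
unbounded grid; ring means divide by the number of *valid* members, so
cortex edges do not bias them; a Euclidean-ring mode exists).  Iron is
put on the marker's scale by

    s = median(marker counts | pixels with ≥ 1 object)
      / median(iron counts | pixels with ≥ 1 object)

and the model predicts `Σ_k C_k · s · ringmean_k`.  Coefficients live
on a 0.01 grid with `C_pixel ≥ C_ring1 ≥ … ≥ 0` and an exact sum of
1.00 (integer hundredths internally — the simplex constraints can never
drift in floating point).  The search is exhaustive (8037 combinations
for three rings), minimizing the per-pixel mean absolute difference
between predicted and actual marker counts; ties break toward the most
local combination, with the tie count reported.  A strict-inequality
chain mode exists.  The per-section *residual* rescales the error by
the median marker count over marker-containing pixels (multiply by
default, reproducing the displayed convention; a divide mode is
provided — within a section both order models identically, which the
suite verifies).  Sections with fewer than 10 fit pixels, or with no
object-containing pixels in either map, are skipped and logged.

The mean (rather than summed) absolute error leaves the per-section
argmin unchanged but makes residuals comparable across sections of
different size; a sum mode is provided.

## Statistics

* Friedman rank test, tie-corrected, with Kendall's
  W = χ²/(n(k−1)) — W is 1 under perfect concordance.
* Skillings–Mack for incomplete blocks: within-block midranks, scaled
  centered rank sums `A_j = Σ_i √(12/(s_i+1))(r_ij − (s_i+1)/2)`, and
  the quadratic form `A'Σ⁻A` with the co-occurrence covariance and a
  Moore–Penrose inverse; χ² with k−1 df.  On complete tie-free designs
  this reduces exactly to Friedman, which the suite asserts at 1e−8.
* Conover all-pairs post hoc from within-block rank sums with
  (n−1)(k−1) df, Benjamini–Hochberg adjusted.
* One-way repeated-measures ANOVA (partitioned sums of squares) with
  Tukey HSD pairs via the studentized range on the within-subject error
  mean square.
* Mixed models (statsmodels MixedLM): crossed random intercepts for
  subject and cortical region (variance components on a single group),
  fixed effects age at death and sex, with and without iron density;
  maximum-likelihood fits so the likelihood ratio between the nested
  models is valid, with AIC/BIC from the same fits, the iron slope with
  a Wald 95% interval, and marginal/conditional (Nakagawa) R² — both are
  reported because "total variance explained" is ambiguous.  Before
  comparison, subjects with Cook's distance above 4/n (computed on the
  fixed effects from leave-one-subject-out refits) are removed.

All p-values are two-tailed; α = 0.05.

## Synthetic cohorts

No human material ships with the package; a generator with planted
ground truth makes every stage testable.  Defaults describe one cohort
of 19 cases sampled in four lobes, three stains per site:

* **Geometry** — a cortical ribbon 24 mm wide and ≥ 5 mm deep at 50 μm
  raster resolution, pial surface a sinusoid (300 μm amplitude, 4 mm
  period, random phase), deep side on the raster edge.
* **Iron** — Poisson counts per cell with intensity
  `exp(−depth/500 μm)` times a multifocal lateral profile: Gaussian
  foci (widths 150–400 μm, lognormal amplitudes, ~0.8 foci/mm) over a
  2% background, ~12,000 expected objects/section (~100/mm²).  The
  multifocality matters twice over: siderosis is a patchy,
  sulcus-centred process, and a laterally uniform gradient makes the
  ring model unidentifiable (every ring mean of a locally linear field
  equals the centre value).
* **GFAP** — per 500 μm pixel, a sparse layer baseline
  (0.3/0.2/0.1/0.05/0.05 expected cells; the emulated detector counts
  reactive astrocytes, which are rare in deep cortex) plus a response
  `B · Σ_k C*_k · ringmean_k(iron)` with planted
  C* = (0.55, 0.25, 0.15, 0.05), realized as Poisson counts placed
  uniformly within each pixel's in-cortex cells.  In the default
  `self` scale mode, B is solved per section by a fixed point so that
  the analysis's own median-ratio scale factor, evaluated on the
  realized marker, equals B — the condition under which the ring fit's
  estimand is exactly C*.  A `fixed` mode plants a plain gain instead.
* **CD68** — homogeneous over the cortex, ~6,000 expected
  objects/section; no iron response (the null marker).
* **Misalignment** — adjacent marker sections are deformed by a smooth
  displacement field (translation up to ±(200, 120) μm plus a 100 μm
  sinusoid) tapered to zero at the deep and lateral raster edges:
  slide frames are tissue-cropped, so section-to-section misalignment
  presents as interior distortion, which registration is then asked to
  undo.  Points are moved by the field's fixed-point inverse so mask
  and points stay consistent.
* **Macrohemorrhage** — iron intensity multiplied (×20) inside a 1 mm
  focus, and CD68 given a response proportional to the *excess* focal
  iron, so a CD68–iron association exists only in this scenario (and a
  multiplier of 1 leaves the section unchanged).
* Per-(case, region, stain) random substreams are derived from the
  master seed, so identical configurations reproduce identical cohorts.

What the generator does *not* emulate: stain appearance and detection
noise (false positives/negatives), folded gyral topology, anisotropic
section compression, vascular anatomy, and between-case pathology
correlation structure.  Passing tests therefore demonstrate that the
pipeline recovers what it is designed to estimate under its own model
assumptions — not that those assumptions hold in tissue.

## Problem sizes in the test suite

The suite verifies: exact simplex constraints; identity of the
vectorized search with a per-combination brute force on random 20×20
maps; nested-model monotonicity of the best error over 100 sections;
error-zero recovery of generatively constructed markers (with the
scale factor held at the value used to build them — recomputing the
median from the constructed map would change the scale and the
construction would no longer be its own fixed point); recovery of the
planted C* within ±0.05 per coefficient in ≥ 90% of 100 sections;
count conservation over 50 random warps; the rank-statistic
reductions; and scaled-down directional analogues — decreasing iron
layer profiles over 50 sections, increasing GFAP category profiles
with omnibus significance in ≥ 90% of 20 cohorts of 19 sections, and a
500-replicate null CD68 calibration whose rejection count must land in
the exact binomial 95% band around α = 0.05 (run on flat, grid-aligned
geometry so every pixel is full-area and the no-association null holds
exactly; see the edge-confound note above).
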