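# Methods

This note documents the models implemented in `adipo3d`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect reported values.

## Coordinate and unit conventions

Arrays are channel-first `(C, Z, Y, X)`; label stacks `(Z, Y, X)` with 0
as background. All physical quantities are micrometres; `spacing` is the
per-axis voxel pitch `(z, y, x)`, default isotropic 1.15 µm, matching a
typical cleared-tissue confocal acquisition (stacks of roughly 300 µm
depth, ≈ 260 planes). Connectivity is 26-neighbour throughout; distance
transforms are computed in physical units so anisotropic spacing is
handled transparently.

## Synthetic tissue generator

The generator exists so that segmentation, morphometry, QC and statistics
can be validated against known ground truth.

**Diameter distributions.** Cell diameters are lognormal, parameterized
by arithmetic mean *m* and coefficient of variation *cv*
(σ² = ln(1+cv²), µ = ln m − σ²/2), so that a preset's mean is directly
comparable with a published depot mean. A mixture of lognormal
components models bimodal depots. The built-in presets use published
depot means (visceral 81.32 µm, subcutaneous 63.88 µm for trout; one
~100 µm population for Swiss-mouse subcutaneous tissue, two peaks at 38
and 50 µm for C57Bl6). No dispersion is published for any depot, so the
CVs (0.30 visceral, 0.35 subcutaneous — subcutaneous depots are reported
as the more heterogeneous) are free generator parameters, not
measurements.

**In situ packing.** Sphere seeds with the drawn radii are placed
uniformly at random, entirely inside the stack, and relaxed by symmetric
pair displacement until no pair overlaps by more than 10% of its radius
sum. Each voxel within a seed's radius is then assigned to the seed with
minimal power distance ‖x − c‖² − r² (a Laguerre tessellation clipped to
the union of seed spheres), which turns residual overlaps into shared
flat facets — the angular outlines of matrix-constrained cells. An ECM
gap of `ecm_thickness` (default 2.3 µm; 3.45 µm for the denser
subcutaneous matrix) is carved along walls between neighbouring cells.
When the requested wall is about one voxel wide the carve removes a
single voxel layer from one side of the wall; carving one voxel from
*each* side would double the physical wall width.

Clipping and carving remove volume, so the clip radii are re-solved
before voxelization such that each cell's final volume matches its
target sphere volume: the spherical caps lost to power planes and the
wall slabs lost to the carve follow from the relaxed geometry in closed
form, and three fixed-point iterations on V(r) = V_target suffice. With
this compensation the ground-truth mean diameter tracks the drawn sample
mean to about 0.1%, so recovery errors measured downstream are
attributable to segmentation and QC, not to the generator. The default
fill fraction for auto-sized stacks is 0.50; cells are placed with a 5%
radius margin from the stack faces so border-truncated cells (which the
QC stage would drop with a size bias, since large cells hit borders more
often) do not occur unless a caller packs a stack manually.

**Ex situ packing.** Non-touching digitized spheres placed largest-first
by rejection sampling. The default surface gap is two voxel pitches,
which guarantees at least one empty voxel between digitized surfaces.
Failure to place a sphere within the retry budget raises an error that
reports how many were placed. The default fill fraction is 0.15,
emulating a dilute extracted-cell preparation.

**Rendering.** Channel 0 (ECM) is a bright shell of `ecm_thickness`
lining every cell boundary on the background side; channel 1 (lipid) is
a uniform interior. Extracted-cell stacks carry the lipid channel only.
Both channels are multiplied by exp(−z·Δz/L) where L is the attenuation
length (the clearing-quality parameter: presets use 150 µm for a
refractive-index-matched, cleared sample and 60 µm for an uncleared one,
a 2.5:1 ratio inside the 2–3× depth gain reported for aqueous clearing),
then offset by a constant background and corrupted with additive
Gaussian noise clipped at zero (defaults: sd 4 and background 2 on
signals of amplitude 100–120).

**What is not emulated.** No point-spread function, spectral
bleed-through, mosaic stitching seams, nuclei, or partial-volume
intensity mixing; real in situ cells are also more irregular (lower
sphericity, 0.6–0.8) than the gently faceted Laguerre cells generated
here (≈ 0.95). Passing tests therefore demonstrate correctness of the
measurement and statistics pipeline on geometrically known inputs, not
segmentation robustness to real optical artefacts — for real data the
intended path is an externally trained segmenter whose label stacks
enter at the measurement stage.

## Segmentation

A classical marker-controlled watershed, deliberately simple and fully
deterministic. Two-channel stacks: both channels are Gaussian-smoothed
(default σ 1.0 µm — about half the default wall width; wider kernels
bleed lipid signal across one-voxel walls and merge neighbours);
foreground is voxels bright in lipid (Otsu threshold unless fixed) *and*
lipid-dominated (lipid > ECM), a comparison that is invariant to depth
attenuation because both channels decay alike. Seeds are the h-maxima of
the Euclidean distance transform, with depth h = `h_maxima_depth` ×
expected radius (defaults 0.25 and 60 µm in situ / 40 µm ex situ), then
seeds closer than `min_seed_separation` (15 µm) are merged; the
watershed runs on the negated distance map restricted to the foreground.
Single-channel stacks: threshold, fill holes, same watershed split. All
resolved thresholds are echoed into the run manifest. Blank stacks yield
zero labels rather than an error.

Predicted and ground-truth labellings are scored by greedy one-to-one
matching on descending intersection-over-union; counts are invariant to
relabelling either side.

## Morphometry

Volume is voxel count × voxel volume — exact for a labelled mask.
Equivalent diameter and sphericity are the closed forms given in the
README. Surface area is the area of the marching-cubes isosurface
(level 0.5) of each cell's zero-padded binary mask, relaxed with 10
volume-preserving Taubin smoothing passes (λ = 0.5, ν = 0.53) before the
area is taken: the raw staircase mesh of a binary mask overestimates
curved areas by ~9%, which would depress every sphericity by the same
factor, while planar faces are unaffected by the relaxation. With this
estimator a digitized sphere of radius 25 voxels measures sphericity
≈ 0.98 and a cube ≈ 0.82 (analytic value 0.806). Objects smaller than 27
voxels are left unsmoothed (their meshes would collapse); sphericity of
tiny digitized objects can exceed 1 and is reported unclamped. The
estimator name is recorded in table provenance because absolute
sphericity is estimator-dependent — comparisons across software using,
e.g., Crofton-type estimators should compare contrasts, not absolute
values.

Centroids are voxel-centre based (0-based index × spacing). Border
contact tests the six stack faces; the stack is treated as the fused
mosaic.

## Mask QC

Filters apply in the order manual exclusions → border → voxel-count
floor → sphericity floor, all strict (`< floor` removes). They are
conjunctive, so the retained set is order-independent; only the
attribution of removals in the report depends on the order. The volume
floor is defined in voxels (5000) at the 1.15 µm reference pitch because
that is how such floors are specified in practice; `QCParams.for_spacing`
carries the same physical volume (7604.375 µm³ ≈ 24.4 µm equivalent
diameter) to stacks at another pitch. The report conserves counts:
input = retained + Σ removals.

## Statistics

**KDE.** Gaussian kernels with the Silverman rule-of-thumb bandwidth
0.9·min(sd, IQR/1.34)·n^{−1/5} (the default of common density-plot
implementations), evaluated on a 512-point grid spanning the data range
± 4 bandwidths. The 4-bandwidth margin (rather than the conventional 3)
keeps the trapezoidal integral within 10⁻³ of 1 even when the sample
mass sits at the range edges.

**Permutation KS.** D is computed on right-continuous ECDFs at pooled
values; internally both observed and permuted statistics are held as the
integer |n₂·cumₐ − n₁·cum_b| so exceedance comparisons are exact, with
ties counted as exceedances (conservative). The pooled sample is
re-split m = 10 000 times (Monte-Carlo, not enumeration) into groups of
the original sizes and p = (b+1)/(m+1), which is strictly positive with
minimum 1/(m+1). Permutations re-split at the cell level, matching a
test on pooled per-cell distributions; sample-level (per-animal)
permutation is a possible extension, not implemented.

**Effects model.** OLS of a per-sample summary (mean diameter or mean
sphericity) on tissue + sex + body weight. The model is fit on
per-sample means, not per-cell values: thousands of cells per sample
would otherwise pseudo-replicate the tissue effect. Single-level factors
and rank-deficient designs raise errors naming the offending term.

## Problem sizes used in tests and the reproduction script

The blind two-depot recovery runs at a 2.3 µm pitch (twice the reference
acquisition pitch) with ~300 cells per depot, which keeps a full
simulate→segment→measure→qc→compare cycle around two minutes on one CPU;
the QC floor is carried over as the same physical volume (625 voxels at
2.3 µm). Cells of 60–80 µm remain 26–35 voxels across at this pitch, so
digitization error is negligible relative to the 5% recovery check.
Segmentation recall is evaluated at the native 1.15 µm pitch on a ~30
cell tissue. The type-I calibration uses 200 null replicates of 100 vs
100 samples at m = 2000 permutations each; the single-dataset
calibration against the classical two-sample KS null uses 200 vs 200 at
m = 10 000.

## Known limitations

- The watershed segmenter is validated on rendered synthetic stacks; it
  is a baseline, not a replacement for a trained model on real images.
- Global Otsu thresholding degrades for strongly attenuated stacks
  (attenuation length ≪ stack depth); the channel-comparison foreground
  helps, but depth-adaptive thresholding is not implemented.
- Laguerre cells are convex-ish; concave or ruptured cells are outside
  the generator's vocabulary.
- The Phipson–Smyth exact-enumeration refinement for small pools is not
  implemented; at m = 10 000 the (b+1)/(m+1) estimator is adequate.
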