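# Methods

This note documents the models, parameters and numerical choices behind
`axonquant`, and what the synthetic-data validation does and does not show
about real microscopy data.

## Coordinate and intensity conventions

Volumes are `(z, y, x)` arrays with one isotropic physical voxel size
(default 0.09 µm); world coordinates are micrometres from the centre of
voxel `(0, 0, 0)`. Intensities are arbitrary detector counts, stored as
8/16-bit TIFF; no background subtraction or normalization is applied
anywhere, and fluorescence is reported in raw arbitrary units.

## Synthetic axon stacks

The generator emulates thin, bright axons on a dark background as imaged at
high magnification with isotropic sampling:

- **Centerlines** are cubic-smoothed correlated random walks: a unit
  direction perturbed by Gaussian angular noise (sd = `tortuosity`, default
  0.15 rad per µm of arc) at 1 µm control spacing, reflected at the stack
  margins, interpolated with a cubic spline and resampled at 0.03 µm so
  chord sums track the smooth curve. Total length is the exact polyline
  length of this fine sampling.
- **Tube profile**: isotropic Gaussian cross-section with sd =
  `axon_radius_um / 2` (default radius 0.16 µm, i.e. 0.32 µm diameter), so
  the nominal radius sits at the visible ~2 sd extent of a
  diffraction-blurred thin neurite. Overlapping structures combine by
  maximum, not sum.
- **Boutons** are brighter Gaussian spheres (sd = `bouton_radius_um / 2`,
  default radius 0.4 µm; amplitude 1.8× the tube peak) centred on the
  centerline at Poisson-distributed arc positions (default rate
  0.15 µm⁻¹, a realistic en-passant bouton density for subcortical
  axons), with an option to add terminal ("drumstick") boutons at the
  centerline endpoints.
- **Noise**: Gaussian read noise (default sd 20 counts on a background of
  100 and tube peak of 2000) plus optional Poisson shot noise. The defaults
  are calibrated to geometry only (voxel size, axon diameter); no published
  intensity statistics exist for the stacks this emulates, so the noise
  level is a package choice representing clean confocal data.
- All randomness flows from one integer seed; identical parameters give
  bit-identical stacks.

What this phantom does **not** model: the anisotropic optical PSF, spectral
bleed-through, depth-dependent attenuation, tissue autofluorescence and
deformation, or axons thinner than the nominal diameter. Passing the
recovery tests therefore demonstrates correctness of the measurement chain
on ideal tube geometry, not performance on degraded real images.

## Bouton segmentation

A random forest (100 trees, stored seed) classifies voxels as
bouton / axon / background from 7 + 3·n_scales features per voxel: raw
intensity, Gaussian smoothing, gradient magnitude, Laplacian of Gaussian
and difference of Gaussians at the smallest scale, 3×3×3 neighbourhood
mean and variance, and the three Hessian eigenvalues (sorted ascending) at
each analysis scale (default 1, 2 and 4 voxel widths). All filters use
mirror boundary handling to avoid edge artifacts in small stacks. Three
label classes are used even though only the bouton mask is consumed
downstream; the explicit axon class sharpens the bouton/shaft boundary.
Training labels come from synthetic ground truth (voxels inside bouton
spheres → bouton, within the axon radius of a centerline → axon, a 2%
subsample of distant voxels → background), so no manual annotation is
involved; a model trained on real annotations can be dropped in through the
same `BoutonClassifier` interface.

## Tubeness, thresholding and the default threshold rule

The tube score is the classical bright-tube measure √(λ₂λ₃) for
λ₂, λ₃ < 0 after Gaussian smoothing at σ = 0.32 µm (σ/voxel ≈ 3.56),
with eigenvalues sorted descending by signed value. σ below the voxel size
is rejected as undersampled; dark-on-bright structures are out of scope.

Binarization is two-level hysteresis: voxels ≥ `high` (and > 0) seed the
mask, voxels ≥ `low` (and > 0) are kept iff 26-connected to a seed;
`low = high` degenerates to plain thresholding. Default levels are derived
from the nonzero-score histogram by a **two-stage Otsu**: a first Otsu cut
discards the faint halo that smoothing at σ spreads around every tube, and
a second Otsu on the remaining scores sets `high`; `low = 0.5·high`. The
two-stage rule matters: a single Otsu pass on the halo-dominated histogram
lands far too low, the mask fattens to several times the tube width, and
the skeleton of a fat curved tube picks up spurious side branches that
inflate the measured length by tens of percent. With the two-stage default,
recovered density on noiseless phantoms is within ~5% of ground truth
across seeds; both levels remain overridable for data with different
statistics.

## Skeletonization and length

3D thinning uses Lee's topology-preserving algorithm (via scikit-image),
the same algorithm family as the standard ImageJ 3D skeletonization
plugins; it is idempotent and preserves connected components. Length sums
each *unique* 26-adjacent voxel pair once — a·1, a·√2, a·√3 for face, edge
and corner adjacency — which avoids the systematic 2× bias of per-voxel
neighbour counting; isolated voxels contribute nothing. Known biases of
the full chain: tube ends erode by roughly the tube radius during thinning
(a few percent on 5-µm-scale stacks), bouton removal cuts the skeleton at
each bouton site (so measured shaft length underestimates total centerline
length in bouton-dense stacks by design), and digitized diagonal paths
carry a small positive length bias. Stack volume is always shape × voxel
size cubed.

## ROI grid and region assignment

Windows of 89.51 µm side are tiled from an origin corner at 100 µm
spacing; windows not fully inside the image are kept but excluded, so the
tiling never depends on image content and the grid extent is a
configuration input rather than a constant. Region assignment is the
majority label over the window's pixels; an exact tie, or a majority of
unlabelled pixels, excludes the window — ambiguous squares are omitted
rather than forced. Line profiles average bilinear samples over a
perpendicular band at each arc-length step; a band of one pixel degenerates
to nearest-line sampling.

## Count normalization and the phenotype rule

Per-animal region fractions are 100 × count / animal total, with
tracer-spread rows excluded from numerator and denominator; fractions plus
remainder sum to 100 exactly per animal. Region summaries are mean ± SEM
across animals (n−1 standard deviation, appropriate for small animal
cohorts); regions whose mean fraction falls below the reporting floor
(default 3%) pool into a "scattered/other" remainder. The phenotype ratio
is r = vGLUT2 fraction / vGAT fraction with the **closed** band
[0.2, 5] classified as mixed and zero denominators mapping to the
corresponding extreme; with this convention "ratio < 0.2" literally means
at least five times more GABAergic cells, matching the worked example of a
GABAergic region at r = 0.18. The rule is scale-invariant by construction.
(The ratio is sometimes verbally named in the opposite order in the
literature this implements; the convention here follows the threshold
semantics and the worked example rather than the name.)

## Statistics

Correlations use the t-transform of r for two-sided p-values; zero-variance
input is an error rather than r = NaN. The unpaired t test uses pooled
variance (df = n₁+n₂−2), the paired test difference scores (df = n−1).
One-way ANOVA reports F with (k−1, N−k) df and Tukey HSD adjusted
pairwise p-values from the studentized range. Repeated-measures ANOVA
applies the Greenhouse–Geisser correction (via pingouin), reporting the
corrected fractional df and corrected p whenever more than two conditions
are present; its post hoc table is Tukey HSD on the condition values. No
correction is applied across separate correlation analyses. Calibration is
checked empirically: over 10,000 simulated null datasets (3 groups × 6),
the one-way ANOVA type-I error at α = 0.05 is 0.05 ± 0.01.

## Problem sizes used in validation

Synthetic validation runs on 48×72×72-voxel stacks (≈ 4.3×6.5×6.5 µm)
with 2–4 axons for density recovery and 3 axons at 0.3 boutons/µm for the
segmentation stage, 300×300 µm fields for the grid analyses, and count
tables of 3 animals per genotype with 350–650 cells each. These sizes were
chosen so each property is measured well clear of small-sample noise while
the whole suite stays fast to iterate on; all of them scale up through the
same APIs.

## Known limitations

- Accuracy on real data depends on the classifier's training annotations
  and on threshold levels appropriate for the data's noise; the shipped
  defaults are tuned to the synthetic phantom's statistics.
- Axons thinner than σ or dimmer than the hysteresis low level are missed;
  crossing axons can fuse into one skeleton branch point.
- The grid's region calls require a user-supplied label map (mask or
  polygons); no automatic anatomical parcellation is attempted.
- Densities from bouton-dense stacks underestimate total centerline length
  (shaft-only measurement, by design).
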