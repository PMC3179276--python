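# Methods

This note documents the models, numerical choices and known limitations
of the `hrpqct` pipeline, in the order data flows through it.

## Calibration and thresholds

Volumes carry density in mg HA/cm³ on an isotropic grid (default 82 µm).
The clinical protocol states its fixed segmentation thresholds as
fractions of the scanner's positive integer range — 16% for the cortical
shell, 40% for the filtered trabecular image — without stating the
range's density equivalent.  We therefore expose the mapping as explicit
configuration (`IntensityScale`): full-scale density defaults to
2000 mg HA/cm³, giving absolute thresholds of 320 mg HA/cm³ (cortical)
and 40% of the rescaled filter output (trabecular).  These are config
keys, not claims about any particular scanner.

Geometry bookkeeping is exact integer arithmetic: a 9.02 mm region at
82 µm is 110 slices; a 126 mm field of view reconstructed on a 1536
matrix gives 82 µm voxels.

## Synthetic phantoms

The generator rasterizes an idealized peripheral bone at 3× supersampling
and block-averages mineral occupancy to the acquisition grid, producing
the fractional-density boundary voxels that fixed thresholds must deal
with.  Geometry: a circular cortex of constant thickness whose outer
radius tapers 0.5%/mm along the axis (the axial gradient that area-based
registration relies on); enclosed intracortical pores (axial cylinders
and spheres, rejection-sampled at least one voxel inside both cortical
surfaces, so enclosure is guaranteed by construction); a three-axis
trabecular rod lattice; an optional second bone for tibia quadrant axes.
Defaults are study-like: tissue density 1100 mg HA/cm³ (deliberately
below the 1200 compact-bone constant so the densitometric BV/TV carries a
documented negative bias relative to the voxel-counted truth), lattice
spacing 0.55 mm (Tb.N ≈ 1.8 mm⁻¹), rod radius 0.10 mm, pore radius
0.12 mm.

Ground truth is counted on the pre-blur label image at acquisition
resolution (majority vote over the 27 subvoxels), so truth and
measurement refer to exactly the same rasterized geometry.

Follow-up scans re-rasterize the same anatomy with the scan window
shifted by an integer slice count (repositioning error), apply
morphological perturbations on the supersampled labels — endocortical
apposition/resorption, trabecular thinning, pore growth, all via exact
Euclidean distance thresholds — and rerun the same partial-volume and
noise path.  A zero change reproduces the baseline bit-for-bit.

What the phantoms do *not* emulate: plate-like or anisotropic trabecular
topology, cortical lamellae, non-circular cross-sections, beam hardening,
reconstruction artifacts, or motion.  Passing recovery tests on phantoms
therefore demonstrates correctness of the measurement chain on known
geometry, not clinical accuracy on real anatomy.

## Segmentation

**Periosteal contour.**  Gaussian presmoothing (σ = 1 voxel), an initial
threshold at the cortical absolute threshold, then one half-maximum
refinement: the final contour is taken at 50% of the measured tissue
density (median of the above-threshold smoothed values).  The refinement
matters twice: a fixed low threshold localizes a partial-volume edge
~0.6 voxel outside the true surface, and on noisy data an unsmoothed
threshold contour jitters by whole voxels, which corrupts the area
profiles used for registration.  Per slice the procedure is: threshold,
closing (radius 5), largest connected component (a fibula is dropped by
size), hole fill.

**Standard cortex.**  3D Gaussian (σ = 1 voxel, truncated at 3σ) then the
fixed 16% threshold inside the periosteal mask, largest component.  On
dense rod lattices the smoothed trabeculae can exceed the threshold and
attach to the shell; this is a faithful property of the fixed-threshold
route (the reason an extended method exists), not a defect we correct.

**Extended cortex (autocontour).**  The medullary space is recovered as
the largest connected sub-threshold component inside the periosteal
region, closed per slice with radius 8 (bridging pores and
trabecular-contact gaps of up to ~0.6 mm) and hole-filled; the cortical
compartment is everything between the periosteal and that endosteal
boundary, and the mineralized cortex is the compartment's above-threshold
voxels.  The mineral/void split inside the compartment uses the *raw*
densities: σ = 1 smoothing fills in pores whose radius is near one voxel
(measured: porosity 0.15% instead of 5.15% on a pore phantom).

**Pores.**  Stage 1 labels void voxels per 2D slice (4-connectivity) and
keeps components touching neither the exterior nor the medullary
background; stage 2 region-grows from those seeds through compartment
void space with 26-connectivity, following canals along the axis.  Void
classification defaults to the full-width-half-maximum criterion — the
pore boundary at half the median cortical tissue density — because a
fixed 320 threshold places the boundary at the 71% pore-occupancy level
and undercounts voxel-scale pores by a third; the fixed-threshold
convention remains available (`void_threshold="cortical"`).  No minimum
pore size is imposed by default.  Compartment void voxels that the pore
logic does not claim (thin partial-volume shells) are absorbed into the
cortical mask so that periosteal = cortex ∪ pores ∪ trabecular region is
an exact partition.

Known limitation: at rod–cortex junctions of dense lattices, enclosed
sub-threshold pockets are claimed as pores, overshooting the planted
porosity on the full lattice phantom (~+30% relative at Ct.Po ≈ 5%); on
enclosed-pore phantoms without such junctions the recovery is within 10%.

**Trabecular extraction.**  Frequency-domain Laplace–Hamming filter: a
radial Hamming low-pass window (cutoff 0.8 × Nyquist) times the blend
`0.2 + 0.8·(f/f_Nyq)²`, i.e. smoothing plus edge enhancement.  The
filtered output is rectified at zero, rescaled by its maximum over the
trabecular region, and thresholded at 40%.  The cutoff, blend weight and
rescaling convention are config keys; the defaults were chosen so the
extracted structure volume tracks the rasterized truth within 15% across
lattice spacings 0.45–0.70 mm and noise up to 10% of tissue density.
The signed min–max rescaling convention is available but extracts
roughly twice the true structure volume on these phantoms.

## Morphometry

Densities are plain means over masks.  BV/TV = Tb.vBMD / 1200 (clipped
at 1 with a warning); Tb.Th = BV/TV / Tb.N and Tb.Sp = (1 − BV/TV) / Tb.N
by plate-model assumptions, so Tb.Th·Tb.N = BV/TV and Tb.Sp·Tb.N =
1 − BV/TV hold exactly on every record.

**Tb.N.**  Mid-axes by 3D thinning (`skimage.morphology.skeletonize`);
spacing by directional intercepts: the skeleton is dilated two voxels
transversely to each probe axis, runs of skeleton voxels along a probe
line collapse to their midpoint, runs longer than 4 voxels (a mid-axis
lying along the line) are discarded, and gaps outside [0.5, 1.6] × median
are trimmed as skeletonization artifacts (a missed crossing doubles a
gap; a spur halves one).  Tb.N = 1 / mean gap; Tb.1/N.SD = SD of gaps.
Validation on rod lattices: ≤5% error at spacings 0.55–0.70 mm on
extracted masks, ≤3% on label-image skeletons.  A maximal-sphere variant
(volume-weighted sphere-fitting on the mid-axis complement) is available
via `method="sphere"`; on an ideal three-axis lattice it overestimates
the spacing by ~18% (the diagonal voids admit spheres of diameter √2·s),
which is why it is not the default.  Note that 3D thinning produces curve
skeletons: plate-like structures collapse to points, so the intercept
machinery is validated against ideal mid-plane skeletons directly.

**Cortical thickness.**  The annular estimate divides the mean per-slice
cortical area (compartment area, pores included) by the mean marching-
squares periosteal contour length (voxel-edge counting would overestimate
perimeters by up to 4/π).  The direct estimate Ct.Th\* is the
volume-weighted maximal-sphere (Hildebrand) thickness of cortex ∪ pores,
so pore surfaces do not bias the endosteal–periosteal distance.  Local
thickness is computed by painting spheres from distance-ridge candidates
in order of decreasing radius; exact on slabs, and within two voxels on
rasterized annuli.

**Ct.Po** = 100·Ct.PoV/(Ct.PoV + Ct.BV), with Ct.BV the mineralized
cortical volume — a normalized volumetric index, monotone in pore
dilation by construction.

## Subregions

The inner/outer concentric split thresholds the per-slice Euclidean
distance to the endosteal boundary, with the threshold found by exact
search over the sorted distance values so the inner area holds 60% of
the trabecular area to within ±1% on every slice (this is well defined
for non-convex endosteal boundaries, unlike contour scaling).  Quadrants
are fixed per scan: at the tibia, the mediolateral axis joins the tibial
and fibular stack centroids (the fibula is lateral); at the radius, the
principal axes of the stack-averaged periosteal section are used, with
the side metadata resolving which semi-axis is medial.  Boundaries run
at ±45° through the centroid; every compartment voxel receives exactly
one of the eight trabecular or four cortical labels.

## Micro-FE

One 8-node hexahedron per bone voxel (mineralized cortex plus extracted
trabecular structure); all elements share one analytically integrated
stiffness matrix (2×2×2 Gauss), scaled by tissue modulus and voxel size.
Components not connecting the two end faces (6-connectivity, so only
face-connected load paths count) carry no load and are removed with a
warning; a structure with no spanning component is an error.

Boundary conditions: distal-face nodes displaced axially by −1% of the
stack length, proximal face fixed axially, lateral translations free
except minimal rigid-body pinning (one proximal node fixed in-plane, a
second on the same node row fixed in one direction — placed so a pure
uniaxial field satisfies all pins).  Under these conditions the apparent
modulus of a fully solid block equals the tissue modulus exactly, which
serves as the pipeline's built-in analytic identity; a fully constrained
("high-friction") mode is available for comparability.  The system is
solved with Jacobi-preconditioned conjugate gradients (relative residual
10⁻⁶) warm-started from the homogeneous uniform-strain field, which is
the exact solution for solid sections and a good initializer otherwise.

Outputs: K = |distal axial reaction| / (0.01·L); E_app = K·L / A_gross
with A_gross the mean periosteal area (bounding-box area for plain
blocks); Ct.LF from per-element nodal forces at the distal face summed by
compartment label (shared nodes are split by each element's own
contribution, which sums exactly to the total reaction).  Failure load
follows the Pistoia criterion: scale the linear solution until 2% of the
tissue volume exceeds 0.7% energy-equivalent strain (√(2U/E) per
element); for a homogeneous block this gives F = 0.7·K·0.01·L exactly.
Pore occlusion converts pore voxels to cortical elements and reports
ΔK_PO, ΔE_PO, ΔF_PO as percent of the original model and ΔCt.LF_PO as an
absolute difference; adding material cannot reduce stiffness, so ΔK_PO ≥
0 is asserted, and axial through-pores reproduce the parallel-springs
closed form 100·φ/(1−φ) to better than 1%.

Homogeneous tissue properties are a modeling assumption, not a
limitation to be fixed: compartmental load fractions require identical
material in both compartments.  Geometric and material nonlinearity are
out of scope.

## Registration and longitudinal statistics

The common volume of interest maximizes the Pearson correlation of
mean-removed per-slice periosteal-area profiles over integer offsets
(±30 slices, minimum overlap 50 slices; ties toward the smaller
|offset|).  Pearson rather than a raw dot product makes the match
insensitive to global area change between visits.  On noiseless tapered
phantoms any planted shift up to the search bound is recovered exactly;
at noise of 10% of tissue density, recovery is within one slice.
Subvoxel offsets and full 3D rigid registration are out of scope.

Percent change is 100·(x_v − x_0)/x_0 per subject (absolute change for
biomarkers); Spearman correlations use mid-ranks with the t
approximation (n − 2 df) and pairwise-complete deletion, with an exact
permutation p-value available for n ≤ 10; both choices are config.  The
cohort simulator plants group-specific mean percent changes and
between-variable change correlations through a Gaussian copula; its
recovery tests compare the mean estimated Spearman coefficient against
the closed-form expectation for a bivariate normal sample,
E[r_s] = 6/(π(n+1))·[asin ρ + (n−2)·asin(ρ/2)].  Repeated-measures ANOVA
is deliberately not reimplemented: the exported visit table carries
everything a standard statistics package needs.

## Problem sizes and tolerances

The test suite runs phantoms of 10–16 slices at 3–4 mm outer radius
(segmentation, morphometry, FE) and 110 slices for registration; the
acceptance script solves a 40³-element block (~206k degrees of freedom)
and a 20-slice annulus at 8 mm radius.  Recovery tolerances: Tb.N within
10% of 1/spacing, Ct.Po within 10% relative on enclosed-pore phantoms,
Ct.Th\* within 2 voxels, annular Ct.Th within 5% of the closed form,
solid-block E_app within 0.1% of the tissue modulus, concentric inner
fraction within 1 percentage point, equilibrium residual ≤ 10⁻⁴.
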