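# Methods

This note documents the models, numerical choices and limitations of the
`isletvasc` pipeline in the order the method runs.  Conventions used
throughout: axis order z, y, x; the physical position of voxel index *i*
along an axis is *i*·spacing (0-based voxel centres); all lengths in µm.

## Synthetic scenes

The generator emulates two-channel confocal stacks of a zebrafish pancreatic
islet: a cluster of β-cell-like blobs surrounded by curved capillary-calibre
tubes.

**Geometry.** Each tube is a smoothed random walk: waypoints every ~25 µm
along a random chord anchored just outside the islet, jittered laterally with
SD `tube_waviness` (default 5 µm), interpolated by a cubic spline and sampled
every half finest-voxel.  Tubes therefore cross the whole volume, which
avoids skeleton end-effects inside the analysis ROI.  Tube radii vary
linearly along the arc between two draws from `tube_radius_range_um`
(default 4.5–6.5 µm — capillary calibre at the coarse imaging scale used for
cohort work; the validation suite separately exercises 2–8 µm at 0.5 µm
voxels).  β cells are spheres of radius 5 µm (≈ 10 µm cell diameter) with
centres drawn from an isotropic Gaussian around the islet centre whose SD
scales with n_cells^(1/3), giving an overlapping, islet-like cluster.  Both
margins of the tube construction are radius-independent, so a cohort's
diameter scaling rescales radii on an *identical* point set — the mutant
truth is exactly 0.7× the control truth under paired seeds.

**Rasterization.** A voxel is vessel iff its centre lies within r(s) of the
*nearest* centerline sample s of some tube (evaluated exactly via a KD-tree
restricted to a stamped candidate superset); cells are unions of balls.  The
test suite holds this against a brute-force all-voxels oracle, exactly.

**Rendering.** Binary structure × amplitude 0.7 (relative units, full scale
1.0) → anisotropic Gaussian PSF (default σ = 1.5/0.75/0.75 µm, z/y/x) →
background offset (0.15) plus a linear ramp along y (`background_gradient`)
→ noise → quantization to 8 or 16 bits.  Noise is Poisson shot noise on a
photon-scaled signal plus additive Gaussian read noise; the photon scale and
read SD are set so the total background-region SD equals
amplitude / `snr`, split evenly between the two sources.  `snr` is thus peak
signal over background noise SD; `snr=inf` disables noise.

**Seeding.** `SceneConfig.seed` drives geometry (per-tube child streams, so
thinning the tube count does not perturb the surviving tubes) and the default
noise stream; `make_scene(cfg, noise_seed=...)` redraws only the noise.
Identical config + seed is bit-identical.

**Cohorts.** `make_cohort` produces n control + n mutant scenes (default
5 + 5).  Mutant scenes share the control's geometry seeds; the mutant effect
is radii × `diameter_scale_mutant` and tube count × `density_scale_mutant`
(rounded, ≥ 1) — a count thinning, not an intensity change.

**Default study conditions.** 68×136×136 voxels at 3×1.5×1.5 µm
(≈ 204 µm cube) — large enough to contain the 100 µm analysis sphere, small
enough that a ten-scene validation runs in about a minute per pipeline stage
on one CPU; 6 tubes; 30 cells; SNR 10.  The scaled-down cohort phantom used
for end-to-end validation is an 100 µm cube at 2.5×1.25×1.25 µm with a 40 µm
ROI.  When `islet_center_um="auto"` the configured ROI must fit inside the
volume; radii below twice the finest spacing are rejected as unresolvable.

**What the phantoms do not emulate:** depth-dependent attenuation, spherical
aberration, autofluorescence texture, motion, vessel branching topology
(tubes cross but do not branch), non-spherical β cells.  Passing recovery
tests therefore demonstrates correctness of the measurement chain under a
faithful noise/PSF model, not robustness to every artefact of live imaging.

## Segmentation

A two-phase region-based level-set evolution, shared by both channels.
After Gaussian pre-smoothing (`smooth_sigma_um`, default 0.8 µm), the mask
is initialized from the Otsu threshold intersected with the contrast floor,
and evolved in a narrow band: per iteration the region grows by at most one
voxel (binary dilation), curvature regularization is applied, and the region
criterion binds last.  The evolution threshold at each voxel is

    max( (c_fg(x) + c_bg(x)) / 2 ,  c_bg(x) + (contrast_k + w_size)·σ_bg )

where c_bg is a large-scale (40 µm) background field estimated outside the
dilated initialization (tolerating offsets and illumination gradients), σ_bg
a robust background SD (1.4826·MAD of the smoothed image), and c_fg a local
(10 µm scale) mean over the eroded current mask.  The midpoint rule places
the boundary at half the local amplitude — for a symmetric PSF an
approximately unbiased edge localization; the floor implements the working
criterion that structure must stay significantly (≥ `contrast_k` SDs,
default 3) above background.

The three regularization parameters: `w_curvature` (number of curvature
smoothing passes; each is a Gaussian blur of the indicator at the finest
voxel scale *in physical units* re-thresholded at ½ — isotropic on
anisotropic grids and monotone), `w_size` (adds inward speed in σ_bg units;
because every evolution operator is monotone, raising it can never grow the
result), and `contrast_k`.  Defaults: vessels 1/0/3, cells 2/0/3.

Convergence: relative volume change ≤ `tol` (10⁻³) against either of the two
previous iterates (the discrete flow can settle into a period-2 cycle);
hitting `max_iter` (60) emits a `ConvergenceWarning` with the residual.
Post-processing removes 26-connected components below `min_component_um3` or
below the contrast criterion (re-checked per component against the robust
background estimate).  A constant stack returns an empty mask; a vessel mask
covering ≥ 50% of the volume is rejected — vessels are sparse.

The islet centroid is the unweighted mean of cell-mask foreground voxel
centres, in µm.

## Distance field (multi-stencil fast marching)

The unit-speed eikonal equation is solved on the foreground with boundary
data on the background interface.  Initialization: every foreground voxel
within 3 voxel steps of background receives its **exact** distance to the
nearest background voxel centre (KD-tree over the foreground-facing
background surface — the nearest background voxel always lies there).  A
1-voxel seed band was measured to leave a persistent ≈ 0.9-voxel interior
underestimate; the 3-voxel exact band reduces the worst deviation from the
exact Euclidean distance transform to ≈ 0.35 voxels on random masks and
≈ 0.75 voxels at the centre of large spheres.

Marching expands the accepted set through a binary heap; updates solve the
upwind quadratic over orthogonal stencil frames: the axis frame always, plus
each plane-diagonal frame whose two participating axes share a spacing
(diagonal directions are otherwise non-orthogonal in physical space).
Second-order one-sided differences are used where two consecutive accepted
values exist and are causally ordered, falling back to first order near the
interface.  Non-causal solutions drop the farthest axis and re-solve.
Background voxels never feed an update — the boundary condition enters only
through the exact seeds, which keeps the whole field on the voxel
centre-to-centre (EDT) convention.  Accepted seeds are never re-valued.
Empty masks give an all-zero field; an all-foreground mask is an error (no
boundary exists).

## Centerline and diameters

The mask is edge-padded by its maximum radius before 3D thinning
(`skimage.morphology.skeletonize`), so tubes cut by the volume face keep
their skeleton up to the face instead of being rounded off; the result is
cropped back and intersected with the mask.  The skeleton voxel graph
(26-connectivity) is cleaned by removing redundant triangle-diagonal edges
(longest first, only where the endpoints remain connected through a common
neighbour) — without this, junction neighbourhoods decompose into dozens of
spurious micro-branches.  Endpoint spurs shorter than `prune_factor` (1.5) ×
the local radius are pruned, up to three passes.  Maximal degree-2 paths
become branch polylines; interior points are smoothed by two passes of a
3-point moving average (endpoints fixed), which removes the voxel staircase
(a digital 26-chain otherwise overestimates smooth arc length by up to
≈ 8%, and its points wobble around the true axis).

**Radius assignment.**  Near the medial axis the distance field is a tent,
d(q) ≈ r − |q⊥ − axis|, so trilinear sampling at a point offset from the
sub-voxel axis understates r by the full offset.  Each point's radius is
therefore the apex of a tent fit: over six directions n in the plane
perpendicular to the local branch tangent, with probe half-width t equal to
the finest voxel spacing,

    r̂ = max( d(p), max_n  (d(p+tn) + d(p−tn))/2 + t )

This equals r whenever the axis offset is parallel to some n with magnitude
≤ t and never exceeds r while both probes stay under the same tent; wider
probes were measured to bridge neighbouring tents at junctions and inflate
the estimate.  Probes are discarded if they leave the foreground or if
t > 1.2·d(p).

**Convention.**  Radii are reported on the centre-to-centre distance
convention.  An `interface_correction` flag subtracts half the finest voxel
to refer distances to the sub-voxel interface, but is **off** by default: at
the medial axis of a discretized tube the nearest background centre already
lies only ~0.03–0.12 voxels beyond the true boundary (the minimum over
lattice points just outside radius r), so the half-voxel correction
introduces a systematic underestimate of up to one voxel in diameter, which
measurements on rasterized phantoms confirmed.  Diameter = 2 × radius.

Points that fall on background (interpolated distance 0) are an error naming
the branch and point — they indicate a mask/centerline mismatch.

## Spherical-ROI statistics

The ROI is a sphere of fixed radius 0.1 mm (default) centred on the β-cell
centroid.  In-ROI centerline length clips every polyline segment analytically
at the sphere (roots of the quadratic), so tubes crossing the ROI edge
contribute without bias; density = length / (4πR³/3), in µm⁻².  Mean and SD
(population, ddof 0) are taken over the in-ROI per-point diameters; when no
centerline point falls inside, the moments are NaN with a `diameters_defined`
flag — never silently zero.  The capillary count is the number of connected
skeleton components with at least one in-ROI point — an operational
definition of "number of capillaries"; tubes that touch anywhere inside the
volume merge, so it undercounts crossings by design.  Vessel volume fraction
(in-ROI foreground voxels over in-ROI voxels) is carried as a secondary
densiy readout.

"Vessel density" itself is not uniquely defined in the field; centerline
length per volume was chosen as the primary definition because it is
invariant to diameter (the diameter columns carry that information
separately), with volume fraction reported alongside.

## Scalar readouts

* Integrated density: raw sum of voxel intensities over a mask or box
  (identical to region size × mean); empty region → 0 with a warning.
* Cell count: 26-connected components above a physical volume threshold
  (default 30 µm³ in the pipeline — half a 5 µm-radius cell's core).
* Fin regrowth: regenerated area / dorso-ventral fin length (µm), the
  size normalization for fish of different ages.
* Relative expression: comparative-Ct, fold = 2^(−ΔΔCt), with the reference
  Ct as the arithmetic mean of the reference genes' Cts (equivalently the
  geometric mean of their linear quantities — the standard multi-reference
  normalization; one reference gene reduces to plain ΔΔCt).  Technical
  replicates of a (sample, gene) pair are averaged.

## Two-group statistics

Group summaries are mean ± SEM (sample SD/√n; SEM 0 at n = 1, flagged by n).
Comparisons are two-sided at α = 0.05 with no multiple-testing correction,
matching the exploratory single-comparison design the pipeline serves.
Because the protocol wording this replicates ("non-parametric t-Student
Test") is internally contradictory, no silent choice is made: Student t,
Welch t and Mann–Whitney U are all implemented, the default report carries
all three, and every result records its method.  Welch is the recommended
default (unequal variances are the norm between genotypes).  Mann–Whitney
uses the exact null for untied samples of ≤ 8 per group, the tie-corrected
normal approximation otherwise.  Zero variance in both groups with equal
means returns statistic 0, p = 1.

## Validation design and problem sizes

All recovery claims are checked against generator ground truth: distance
field vs exact EDT on twenty random ≤ 40³ masks (≤ 1 voxel); per-tube mean
absolute diameter error on 2–8 µm tubes at 0.5 µm voxels, SNR 10, through
the full segmentation chain (≤ 1 voxel, measured ≈ 0.2 µm); Dice ≥ 0.9 at
SNR ≥ 5 for tubes and well-separated blobs at ≥ 3-voxel radii; ROI density
within 10% and mean diameter within one finest voxel over ten default
scenes; and a 5-vs-5 cohort with a 0.7× mutant diameter effect recovered at
ratio 0.7 ± 0.1 with Welch significance, plus ≥ 80% power over 100
measurement-level cohort replicates at 10% CV.  The null rejection rate of
Welch at n = 5 is calibrated to 0.05 ± 0.02 over 2000 simulations.  Problem
sizes were chosen so the whole validation runs in minutes on one CPU; the
cohort phantom is a deliberately scaled-down version of the default scene
(same generative model, smaller volume and ROI).

## Known limitations

* Capillary count merges touching tubes; it is a lower bound near dense
  crossings.
* The segmentation boundary is approximately unbiased only for structures a
  few PSF widths across; blobs at ≈ 1 voxel radius along a coarse axis fall
  outside the guaranteed recovery regime.
* The fast-marching field carries a ≤ ~0.5-voxel scheme underestimate deep
  inside thick structures; diameters inherit a corresponding sub-voxel
  uncertainty.
* Branch-graph topology (branching angles, tortuosity) is out of scope; the
  adjacency is carried only to support component counting.
* Diameters at junctions reflect the locally larger inscribed sphere, not
  the calibre of either parent vessel.
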