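# Methods

## The problem

Neuropathologic assessment of dementia samples a handful of standard
cortical blocks — middle frontal gyrus (MFG), middle/superior temporal gyri
(MSTG), inferior parietal lobule (IPL), and primary visual cortex (V1) —
from coronal slabs cut at the autopsy bench, using gross landmarks (most
prominently the coronal slice containing the anterior commissure) to decide
where to cut.  `virtsamp` simulates this protocol on volumetric images and
asks three quantitative questions:

1. **Precision** — when the same landmark rules are applied to many brains
   and the resulting blocks are mapped into a common template space, how
   consistently do they cover the same voxels?
2. **Accuracy** — how much of the *intended* region (a template-defined
   target mapped into each subject's anatomy, the *reference* block) does
   each sampling strategy actually capture?
3. **Functional consequence** — when the sampled block misses the reference,
   does it land in functionally different tissue, as measured by seed-based
   resting-state connectivity to a whole-brain region set?

Three sampling strategies are compared on each subject, reusing the same
in-plane footprint:

* **subject-specific** — the bench emulation: the slab is chosen from a
  (noisy) landmark, the in-plane position from local anatomy;
* **guided** — the subject-specific block translated in whole-slab steps
  along the anterior-posterior (AP) axis to the slab maximizing overlap
  with the reference (what a prosector could do with an MRI printout);
* **optimal** — the subject-specific block under the best 6-DOF rigid
  motion (translation + rotation, no scaling/shear/warp), an upper bound on
  what re-positioning the brain before slicing could achieve.

By construction the three strategies are nested (the guided offset is a
rigid motion, and the identity is a guided offset), so for every subject and
region `overlap(optimal) >= overlap(guided) >= overlap(subject_specific)`.
The implementation preserves this ordering exactly by always including the
identity and the guided solution among the rigid search's candidate set.

## Geometry

All geometry lives in RAS+ world millimetres; voxel indices are 0-based and
refer to voxel centers; the AP axis is world *y*.  Coronal slabs are
half-open intervals `[origin + i*t, origin + (i+1)*t)` with thickness
`t = 4 mm` (the brain-cutting protocol's slice interval); a point exactly on
a boundary belongs to the later slab.  The slab origin is anchored at the
minimum AP voxel-center coordinate of the grid (or a user-supplied
coordinate), so every voxel center belongs to exactly one slab.  Slab
membership is evaluated on voxel-center *world* coordinates, so slabs remain
true coronal slabs on oblique grids.

Blocks are axis-aligned rectangles in the coronal plane, 38 x 32 mm by
default (the protocol's 3.8 x 3.2 cm block), extruded through one slab.
Membership is voxel-center-in-box with half-open boxes; there is no
partial-volume weighting, because all downstream overlap statistics are
counts over binary masks.

Percent overlap between a sample and a reference block is
`100 * |sample ∩ reference| / |reference|`.  The reference denominator (not
Dice, not union) is the primary accuracy metric because the scientific
question is "how much of the intended tissue was captured"; `sample`,
`union` and `dice` denominators are available as options.

## Moving masks

Masks are moved by pulling: the moved mask's value at a target voxel center
is the trilinear interpolation of the source 0/1 field at the
inverse-mapped point, thresholded at 0.5.  Trilinear-plus-threshold (rather
than nearest-neighbour) reduces aliasing of the thin 4 mm slab dimension
under rotation and is deterministic.  Transforms may be rigid (three
extrinsic x-y-z Euler angles about a stated center plus a translation),
general 4x4 affines, dense displacement fields, or arbitrary callables on
world points; the last form is how the synthetic cohort's analytic
deformations enter the pipeline without intermediate resampling.

### The guided (AP slab) search

Exhaustive: every integer slab offset that keeps the block on the stack is
evaluated and the offset maximizing percent overlap is returned.  Ties
prefer the smallest |offset| (then the smaller offset), so a hopeless
search returns the original placement.  When the translation is an exact
integer number of voxels on an axis-aligned grid the shift is done by array
slicing, which is both fast and exact.

### The rigid (6-DOF) search

Hard binary overlap is piecewise constant in the transform parameters, so
the search optimizes a smooth surrogate: the inner product of
Gaussian-smoothed (sigma = 1 voxel) soft masks, normalized by the
reference's soft mass.  The procedure is:

1. **Multi-start Powell** on the surrogate (8 starts by default: the
   identity; the centroid-alignment translation; the guided offset when
   supplied; and seeded random perturbations of the centroid start), with
   box bounds of +-20 mm and +-20 degrees.
2. **Nelder-Mead polish** of the best Powell solution on the same surrogate
   evaluated on a 2x supersampled grid.  The supersampling matters: the
   surrogate is a quadrature of a continuous overlap integral, and at native
   resolution its maximizer can sit 2-4 degrees away from the generating
   transform because the quadrature error of a thresholded, staircase-edged
   mask is anisotropic.  Finer quadrature removes most of that bias.
3. **Selection by hard overlap.**  All starts and all optimized points are
   scored by exact binary overlap; the best wins, and near-ties (within
   1e-9) go to the transform of smallest parameter norm (degrees and
   millimetres weighted equally).  Because the identity and the guided
   solution are always candidates, the returned overlap can never fall
   below either — the nesting of the three strategies is enforced exactly,
   not just in expectation.

Rotation is about the reference-mask centroid, which decouples rotation
from translation and conditions the search.  All evaluations are restricted
to a padded bounding box around the reference support (the overlap
numerator can only live there), which keeps a full cohort run cheap.

Parameter-recovery accuracy is voxel-limited: on 1 mm grids the optimizer
recovers generating transforms of up to 15 mm / 15 degrees to well under
1.5 degrees and 1 voxel; on 2 mm grids the *data themselves* (a thresholded
staircase box) are best aligned by a transform a couple of degrees away
from the generating one, so sub-degree recovery there is not an optimizer
deficiency but an identifiability limit.

## Precision and accuracy summaries

The precision surface is the voxelwise count, on the template grid, of how
many subjects' mapped subject-specific blocks cover each voxel.  Histograms
report the share of voxels at each overlap degree k = 1..n; the default
domain is the union of all subjects' masks, the only denominator that is
self-contained (a "whole-map" domain is available).  The accuracy table is
long-format (subject, region, method, percent overlap) with per-(region,
method) mean, unbiased SD, median and IQR; duplicate or missing cells are
hard errors.

## Inference

* **Wilcoxon matched-pairs signed-rank** compares percent overlap between
  methods within subjects.  Zero differences are dropped (Wilcoxon's
  original rule); tied absolute differences get mid-ranks.  For m <= 12
  retained pairs the two-sided p is exact by enumeration of all 2^m sign
  assignments (the null is symmetric about m(m+1)/4, and the p-value sums
  both tails by distance from that center); otherwise a tie- and
  continuity-corrected normal approximation is used.
* **Poisson regression with robust SEs** models overlap voxel counts with a
  log(reference voxel count) offset and method indicators, fitted by IRLS
  to a score norm below 1e-8.  Standard errors come from the sandwich
  estimator clustered by subject — observations within a subject are
  dependent by design — with the Stata-style G/(G-1)*(N-1)/(N-k) factor;
  plain HC0 is available.
* **Sign-flip permutation** builds the null for paired per-region
  differences by randomly negating each subject's whole delta row
  (whole-row flips preserve the within-subject dependence across regions;
  they encode the exchangeability of the two sampling labels within a
  subject).  The per-region statistic is the signed count, (#subjects with
  delta > 0) - (#subjects with delta < 0); the mean delta is available as
  an alternative.  Thresholds are the empirical 5th and 95th percentiles of
  the permutation distribution; a region is flagged when its observed
  statistic falls strictly outside them.  The signed count is discrete
  (its values share the parity of n), so the test's exact size sits
  slightly below the nominal 5% per tail — about 4% per tail at n = 35 —
  which is the expected behaviour of an empirical-threshold test on a
  lattice-valued statistic, not a miscalibration.

## Connectivity

A block's functional profile is the Pearson correlation of its mean BOLD
series with the mean series of each region in a whole-brain set (264
regions by default, 5 mm spheres around supplied or synthetic centers).
Blocks defined on the structural grid are transferred to the functional
grid by trilinear partial-volume weights and averaged with those weights,
so a 4 mm slab contributes proportionally even when functional voxels are
coarser than the slab.  Zero-variance or empty region series are flagged
undefined, never silently zeroed; regions undefined for any subject are
excluded from significance calls.  Correlations are compared on the r scale
(differences of r, not Fisher z, are what the discrepancy analysis
thresholds); a Fisher transform can be applied by the caller if desired.

## The synthetic cohort

The phantom generator produces everything the pipeline consumes, with known
ground truth:

* **Template** (default 96 x 120 x 96 voxels at 2 mm): an ellipsoidal brain
  (semi-axes 72 x 90 x 68 mm) with a sinusoidally modulated "cortical"
  shell, an anterior-commissure-like landmark near the center, four target
  blocks placed on the slab stack at anatomically laid-out positions, and
  264 region centers sampled quasi-uniformly inside the brain (minimum
  separation 11 mm) partitioned into 8 spatially coherent communities by
  k-means.
* **Subjects**: each subject's anatomy is the template under a known
  deformation phi(p) = R p + t + w(p), with R, t a small rigid motion
  (rotation SD 3 degrees, translation SD 5 mm) and w a sum of 4 analytic
  low-frequency sinusoidal displacement components (total amplitude <= 3 mm,
  wavelengths 60-120 mm).  The warp's Lipschitz bound is kept below 0.5 so
  phi is invertible; the inverse is computed by fixed-point iteration and
  both directions are exposed to the pipeline as exact callables — the
  synthetic "registration output" *is* the true transform, which isolates
  the sampling computations from registration estimation.
* **Landmark-driven placement**: the prosector model places each
  subject-specific block on the slab containing the jittered landmark
  (AP jitter SD 6 mm, in-plane SD 3 mm) offset by the region's nominal
  slab-count distance, at the true warped in-plane position perturbed by
  placement jitter (SD 3 mm).  The 6 mm AP figure is a generator default
  chosen to produce slab-level sampling errors of the magnitude the bench
  protocol plausibly incurs (with 4 mm slabs it sends roughly two thirds of
  placements to a wrong slab); it is a tunable model parameter, not a
  measured quantity.
* **BOLD** (default 240 volumes, TR 2.5 s, 3.5 mm functional voxels):
  region latent signals are drawn from a unit-variance covariance with
  within-community correlation 0.6 and between-community correlation 0.05;
  every in-brain functional voxel carries its nearest region's latent
  signal plus white noise (SD 1.0).  Time is white by default (a temporal
  smoothing option exists); the generator makes no attempt at hemodynamics,
  drift, motion, or physiological confounds.

All randomness flows from one master seed through named `SeedSequence`
substreams; a cohort serialized to disk records per-subject truth JSON from
which the whole cohort regenerates bit-identically (BOLD volumes are
regenerated from recorded seeds rather than stored, since a cohort of 4D
series would be hundreds of megabytes).

### What passing tests do and do not show

The phantom shares the real protocol's geometry (slab arithmetic, block
sizes, landmark anchoring) and its statistical structure (between-subject
anatomical variability, landmark error, community-structured connectivity),
so it validates the *computations*: overlap arithmetic, the two searches,
the inference machinery, and the end-to-end direction of the
guided-vs-bench comparison.  It does not validate claims about real brains:
real gyral anatomy, registration error, fixation distortion, and
hemodynamic structure are all absent, and the phantom's effect sizes follow
from its jitter defaults rather than from any measured bench variability.

## Validation experiment design choices

* The rigid-recovery benchmark generates mask pairs on a 1 mm grid, where
  the criterionic 1.5-degree / 1-voxel recovery is identifiable (see above).
* The planted-displacement connectivity experiment centers its two blocks
  on the centroids of the two most separated planted communities, selected
  programmatically from the template truth.  Community recovery is only
  well-posed when each block loads predominantly on one community; blocks
  at the anatomical ROI positions can straddle community boundaries, and
  the significant lists then correctly include spillover regions that are
  not in either planted set.
* Null-calibration simulations use n = 35 subjects (the cohort size of the
  emulated study) and report per-tail rejection rates, the quantity the
  empirical-threshold rule actually controls.

## Numerical choices and degenerate inputs

* sform is preferred over qform; a NIfTI with neither is rejected.  NaNs
  are rejected at load time unless zero-filling is requested.
* Resampling is by pulling (each target voxel center inverse-mapped into
  the source); out-of-source voxels get 0.
* An all-zero transformed mask raises unless explicitly allowed; the slab
  search skips offsets that push the block off the grid.
* Wilcoxon with all-zero differences raises; the accuracy stage catches
  this (the zero-jitter cohort) and reports "no difference" with p = 1.
* Empty regions and zero-variance series are flagged and excluded, not
  imputed.
* Histogram percentages over the union domain sum to 100 by construction;
  the empty overlap map yields an all-zero table.

## Problem sizes

Default validation runs use a 20-subject cohort at 2 mm structural
resolution for the precision/accuracy stages, 25 pairs at 1 mm for rigid
recovery, 500 simulated datasets for permutation calibration, and a
12-subject cohort with 240-volume BOLD for the connectivity experiments.
All sizes are configurable; the defaults keep a complete run on one CPU
core in the tens of minutes.

## Known limitations

* The prosector model reduces human judgment to landmark-plus-jitter; the
  in-plane placement rule in particular is an operationalization, not a
  validated behavioural model.
* The rigid search is a heuristic global optimizer; it carries no
  optimality certificate beyond its oracle tests (it matches exhaustive
  coarse grids and recovers generating transforms within voxel limits).
* Percent overlap against the reference is asymmetric; two methods with
  equal reference coverage may capture different non-reference tissue.
* The permutation test controls per-region tail probabilities; no
  across-region multiplicity correction is applied beyond the empirical
  5% thresholds themselves.
* Estimating nonlinear registrations is explicitly out of scope: the
  pipeline applies supplied (or synthetic ground-truth) transforms.
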