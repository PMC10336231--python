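# Methods

This note documents the models, conventions and numerical choices behind
`cytomap`, and what the synthetic-data experiments do and do not show.

## Gray level index (GLI)

A stained section is binarized (Otsu by default, or a fixed intensity
threshold; cells are dark on a bright background) and reduced to the
fraction of stained pixels per non-overlapping square measuring field,
expressed in percent.  Trailing partial fields are dropped rather than
padded — a padded field would report a biased fraction.  The measuring
field defaults to 16×16 source pixels (≈16 μm at the classical 1.02 μm/px
scan resolution) and is configurable; scaled-down synthetic runs use
5×5 fields at 6 μm/px (30 μm fields).  Downstream sampling interpolates
the GLI grid bilinearly, with each value anchored at its field center.

Two exact invariants are enforced by tests: mass conservation (sum of
fractions × field area = stained pixel count over the covered region) and
monotonicity under adding stained pixels.

## Traverses and laminar profiles

Traverses connect the outer contour (layer I/II boundary, 0 % depth) to
the inner contour (layer VI/white matter, 100 %).  They follow gradient
streamlines of the harmonic field u solving ∇²u = 0 with u = 0 on the
outer and u = 1 on the inner contour and natural conditions on the open
ribbon ends.  Harmonic streamlines cannot cross, which a nearest-point
pairing of contours does not guarantee in curved or folded cortex; between
concentric circular contours the solution is log-radial, and the test
suite verifies traverses there are radial to within 1°.

Numerics: the Laplace equation is discretized with the 5-point stencil on
a regular grid (default step 1 source pixel; coarser steps are used for
scaled-down synthetic runs), Dirichlet values are imposed on a ~0.75-step
band around each contour, and the sparse system is solved directly.
Streamlines are traced with a midpoint (RK2) rule at half-grid steps; the
gradient inside the constant Dirichlet bands vanishes by construction and
is replaced by the nearest interior gradient so streamlines can leave the
outer contour.  Tracing stops at u ≥ 0.995 and the endpoint snaps to the
nearest point of the inner contour.

Profiles are sampled bilinearly along each traverse and resampled by
linear interpolation to D equidistant depth points spanning 0–100 %
(D = 101 by default; the resampling makes all downstream statistics
independent of local cortical thickness, verified to 1 % per feature for
a thickness doubling).

## Feature vectors

Ten elements: mean, center of gravity (% depth), SD, skewness and
kurtosis (non-excess) of the profile, and the same five of its first
derivative.  Moments treat the profile as a weight function over depth —
the center of gravity is the GLI-weighted mean depth — which is the
interpretation consistent with "center of gravity in % depth".  Plain
moments of the value sequence are available via `weighting="value"`.

The derivative (central differences with respect to depth) is rectified
(absolute value) by default: a signed derivative has near-zero mean for
any roughly monotone-free profile, making its shape moments numerically
unstable; `rectify=False` disables this.

Degenerate conventions: an all-zero sequence yields all five statistics 0;
a flat (constant) sequence carries no laminar shape information and yields
zero SD/skewness/kurtosis (mean and center of gravity are kept).

## Border detection

At sliding position *i* the left block covers profiles [i−b, i) and the
right block [i, i+b).  MD² = dᵀS⁻¹d with d the difference of block mean
feature vectors and S the pooled within-block covariance of the 2b member
vectors.  Because b can equal the feature dimension (b = 10, dim = 10),
S is regularized by adding ridge·trace(S)/dim to the diagonal
(ridge = 10⁻⁶ by default); the ridge-free and ridge computations agree to
10⁻⁸ relative error on well-conditioned random data.

Significance: T² = (b·b/2b)·MD² is referred to the F(dim, 2b−dim−1)
distribution after the usual scaling, and Bonferroni-corrected over the
number of sliding positions tested for that block size (the correction
family is per block size per section; a positions×block-sizes family is a
configuration choice, not hard-coded).

A candidate border is a strict local maximum of the MD curve over a ±2
window (ties break toward the lower index) with corrected p < α and not
excluded by the artifact mask (the manual quality-control step is reduced
to this per-position exclusion input).  Acceptance requires maxima at
comparable positions (±4 profiles by default) for ≥3 block sizes within a
section and in ≥3 consecutive sections; the reported position is the
median over the supporting chain.

Calibration: on Gaussian null blocks (dim 10, b = 16, 10⁴ replicates) the
uncorrected test rejects at 4.9 % for nominal 5 %; on homogeneous
synthetic ribbons the full pipeline accepts a border in 0 of the tested
seeds at α = 0.05.

## Area similarity

Feature vectors (10–15 consecutive profiles per area and section,
hemispheres pooled) are standardized to zero mean and unit variance across
samples — the raw features mix percent and percent-depth units, and
unstandardized Euclidean distances would be dominated by the largest-scale
feature — then clustered with Ward linkage.  Both profile-level and
area-mean-level clustering are provided; raw (unstandardized) mode is a
flag.  Cophenetic distances quantify pairwise area similarity.

## Probability maps and MPM

Per-area probability = fraction of subjects labeling a voxel.  The MPM
assigns each voxel to the arg-max area when its probability is positive
and at least the threshold (default 0, i.e. pure arg-max; the conventional
40 % cut is a flag).  Exact ties resolve deterministically: majority area
among the tied candidates' 6-connected neighbors that already have a
unique assignment, then the lowest area id.  Registration to a reference
space is out of scope — cohorts are assumed pre-aligned, which the
synthetic cohort generator provides directly.

## Volumetry and permutation inference

Volume = shrinkage factor × section spacing × Σ delineated areas
(Cavalieri).  Hemisphere comparisons use a paired sign-flip permutation
test on per-brain left/right differences; group comparisons permute group
labels.  P-values use the (b+1)/(m+1) convention (never exactly zero) with
seeded Monte-Carlo null distributions (10⁶ iterations for the published
table); Benjamini–Hochberg adjustment is applied over the comparisons of
one call.  The packaged published table carries shrinkage-corrected
volumes only (whole-brain volumes are not published), so its tests are run
on corrected rather than normalized volumes — an approximation documented
here.  The published summary's final "SD" cell is reproducible only as the
sum of the six per-area SDs; `summarize` additionally reports the SD of
the per-brain totals, which is the statistically meaningful quantity.

## Synthetic histology

The generator renders what the pipeline needs and nothing more: dark cell
disks on a bright background with per-layer target stain fractions, placed
by dart throwing (limited re-throws to avoid overlap, overlap allowed
afterwards), with throwing stopped per depth band when its covered
fraction reaches the target — rendered densities therefore track targets
to within a cell of granularity (verified within 3 binomial SEs per band).
Laminar depth is the normalized distance between contours, the same
coordinate the profile stage measures, so planted ground truth and
measurement share one coordinate system.  Columnarity is a multiplicative
sinusoidal density modulation along the arc (150 μm period).  Geometries:
straight, annulus segment (outer surface on the larger radius), and a
vertically sheared sinusoidal ribbon.

Archetype layer densities are generator parameters on the GLI scale; the
granular archetype has a layer-IV density strictly above both neighbors,
the dysgranular ones do not.  They are patterned qualitatively on
opercular cytoarchitecture but are not measurements of any real area.

Scaled-down study conditions for the detection experiments: straight
ribbons of 2,000 μm cortical thickness and 3.6 mm arc at 6 μm/px, 30 μm
GLI fields, 60 μm traverse spacing (61 profiles), five adjacent sections.
These sizes keep a full multi-seed experiment within minutes while
preserving the per-profile signal-to-noise of the full-resolution setting
(which is governed by the number of cells per measuring-field column, not
by pixel size).

What passing these experiments does not show: robustness to staining
artifacts, vessels, tears or contour-drawing errors (not simulated; the
exclusion mask is the only hook), to registration error in cohorts
(cohorts are generated pre-aligned with rigid jitter only), or that the
invented archetypes match real areas.

## Known limitations

- Blocks overlap across consecutive sliding positions, so neighboring MD
  values are strongly correlated; the Bonferroni correction is therefore
  conservative.
- With traverse spacing below about two GLI fields, adjacent profiles
  share measuring fields and are no longer independent samples for the
  T² test; default spacings keep them ≈ independent.
- The sex comparison on published data is not reproducible (per-brain sex
  labels are not published); the two-sample permutation test is exercised
  on synthetic tables only.
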