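# Methods

This note documents the models and procedures implemented in `coroseg`,
the conventions and defaults that matter, what the synthetic phantoms do
and do not emulate, and the package's known limitations.

## Geometry conventions

Voxel indices are 0-based `(k, j, i)` in `(z, y, x)` array order; world
coordinates are `(x, y, z)` millimetres with
`world = origin + (i·sx, j·sy, k·sz)`.  Grids are axis-aligned (no
direction cosines).  Anisotropic spacing — the clinical acquisition grid is
0.33 × 0.33 × 0.4 mm — is honoured in every millimetre-valued computation
(registration, Hessian scales, surface distances) and ignored in
voxel-count computations (segmented-voxel counts N, the erosion kernel),
matching how such pipelines are specified in practice.

## Stage 1 — multi-atlas heart extraction

Each atlas (image + heart label) is registered to the patient volume as the
*moving* image in two stages, then labels are propagated and fused by
strict majority voting (ties → background; a conservative ROI is preferred
because the downstream stages only ever shrink it).

**Affine stage.**  The cost is the mean squared intensity difference over
image samples redrawn uniformly at random at every iteration; exactly 256
gradient-descent iterations are performed (split evenly across the Gaussian
pyramid levels, default 3).  The gradient is analytic through the trilinear
interpolation of the moving image; out-of-domain samples are dropped from
the per-sample mean.  Steps are scaled so the maximum induced displacement
equals a current step length (default 2 mm, doubled per coarser level) with
backtracking halving on a cost increase evaluated on the same sample set.
The transform is centred on the fixed-image centre for conditioning.

**B-spline stage.**  A cubic free-form deformation (control spacing 16 mm,
lattice covering the fixed domain plus the spline support margin) is
initialized from the affine result and ascends a *localized* mutual
information: each iteration picks one voxel at random and draws the other
samples (default 2048) inside a 50 mm cube around it — "square
neighbourhood" read as its cubic analogue in 3D.  MI uses 32 regular bins
spanning the 1st–99th intensity percentiles, with a cubic-kernel Parzen
window on the moving axis so the derivative with respect to the moving
intensity is analytic (Mattes-style); the chain rule through the trilinear
image gradient and the separable B-spline basis yields the coefficient
gradient.  Defaults: 600 iterations, backtracking ascent, and only the
finest two pyramid levels — the control spacing already regularizes, and
very coarse levels destabilize the histogram gradient.  The standalone
`localized_mi` operation uses a plain (hard-binned) joint histogram, in
bits; it returns 0 with a warning when a marginal occupies fewer than two
bins.

A caution established during development: on *piecewise-constant* images,
interior correspondence is unobservable — stochastic MI ascent can raise MI
while degrading true alignment by overfitting boundary samples.  Deformable
registration of the phantoms is therefore exercised with intra-tissue
texture enabled (below).

## Stage 2 — multiscale vessel enhancement

Hessian components are computed by separable convolution with sampled
Gaussian-derivative kernels (radius 4σ) that are *moment-normalized*: the
weights of each derivative kernel are corrected so constants map exactly to
zero and the monomials x, x²/2 have exactly unit derivative — otherwise
kernel truncation leaves a small DC bias that breaks the bright-line
conditions on ideal inputs.  Scales are specified in mm and converted
per-axis; responses are multiplied by σ² (γ = 2 normalization) for
cross-scale comparability, and the per-voxel maximum over scales
(default 0.5, 1, 1.5, 2, 3 mm — coronary lumen radii at sub-millimetre CTA
resolution) is taken inside the heart ROI only.

Eigenvalues are sorted by magnitude (the convention of the cited line
filter, not the signed-value convention of Frangi-style filters) and scored
with the Sato measure (γ23 = γ12 = 1, α = 0.25, exposed in
`VesselnessParams`).  Two behaviours worth knowing:

* Plates and ideal blobs are suppressed (ratio factor → 0), but *finite
  blobs whose tangential curvature exceeds the radial one* score positive —
  this is a genuine property of the measure, and it is why the phantom's
  blood pool is placed outside the myocardium ellipsoid (see below): the
  heart-ROI restriction, not the filter, excludes adjacent contrast.
* Outside a tube (beyond the profile's inflection) the dominant eigenvalue
  turns positive and the response is exactly zero, so the positive-response
  zone around a tube axis is compact (~1.5 effective scale radii).

## Stage 3 — seed detection

Eligibility is the conjunction `intensity ≥ 120 HU` *and*
`response > vesselness_floor` (default 0): HU is only meaningful on the
original volume, while the enhancement response encodes tubularity — both
signals participate.  Setting `vesselness_floor = -inf` recovers a pure
intensity threshold.  Binary erosion uses a full 4 × 4 in-plane, 3-slice box
(`(dz, dy, dx) = (3, 4, 4)`; the thinner axis is assigned to z to match the
coarser slice spacing, configurable).  Even-sized kernel axes anchor at
`floor(d/2)`; a solid 10³ cube erodes to 8 × 7 × 7.  Every surviving voxel
becomes a seed, in raster order; an empty result is a hard error because
the pipeline cannot proceed.

## Stage 4 — statistical region growing and the v sweep

Seed statistics are the mean and *population* standard deviation over the
seed voxel plus its 26-neighbourhood (border-clipped); the standard
deviation is floored at 1 HU so uniform plateaus still grow.  Phase 1
processes seeds in order, skipping any seed already absorbed (the removal
rule); each remaining seed floods the 26-connected component (connectivity
configurable: 6/18/26; the statistics neighbourhood is always the
26-neighbourhood) of voxels inside `[m − v·d, m + v·d]`, clipped to the
heart ROI.  Phase 2 repeats up to 5 refinement iterations: statistics are
re-estimated over the whole current region, the interval rebuilt, and the
region expanded to closure; a pass that adds nothing ends the loop early.
Growth never leaves the heart mask — ROI clipping is what prevents leakage
through the coronary ostia into the aorta from dominating the counts.

The sweep grows at v = v0, v0 + step, … (defaults 1.0 and 0.1) and stops at
the first jump `N_i − N_{i−1}` exceeding the mutation threshold; the
selected v is the *previous* grid value, the only reading under which the
pre-jump segmentation is the desired one.  Two threshold modes exist: the
absolute voxel-count threshold 1 × 10⁸, and a relative mode (default)
triggering at half the heart-ROI voxel count.  The absolute figure exceeds
the voxel count of a typical 512 × 512 × 300 scan (~7.9 × 10⁷), so it can
never fire on desk-scale data; the relative mode is the robust default and
the absolute value is kept as the documented alternative.  A safety cap
(`max_v`, default 5) ends sweeps that never jump, with a warning.

**Monotonicity caveat.**  Interval nesting makes N(v) non-decreasing on the
pre-mutation branch, and that is what the sweep relies on.  It is *not* a
theorem of the full procedure: past the mutation, statistics re-estimated
over the flooded region are not nested across v, and with the 5-iteration
refinement cap the post-flood counts can dip by a percent or two between
grid values.  The property tests assert monotonicity on the pre-mutation
branch only.

## Evaluation metrics

DICE `2|A∩B|/(|A|+|B|)` (1.0 when both masks are empty); surface voxels are
mask voxels with a 6-connected background or out-of-volume neighbour;
surface distances are *symmetric*: nearest-surface distances between voxel
centres (world mm) pooled in both directions, MSD the pooled mean, MAXSD
the pooled maximum (symmetric Hausdorff).  Nearest distances use a k-d
tree, verified against the O(n²) pairwise definition in the tests.

## The phantom generator

The generator emulates the *intensity ordering* of contrast CTA — lung
−800 HU ≪ myocardium 60 HU < the 120 HU seed threshold < contrast ~300–350
HU — on a simple geometry: a myocardium ellipsoid, curved tubes for
coronary arteries, and a blood-pool ellipsoid *adjacent to* (outside) the
myocardium, modelling nearby contrast-filled blood that the heart-ROI
restriction must exclude.  Design choices:

* **Tube profile.**  Radial Gaussian `peak·exp(−r²/2σ²)` with σ set so the
  wall value is half the peak, truncated at the nominal lumen radius (no
  contrast beyond the wall) — the model of a contrast-filled lumen rather
  than an unbounded halo.  With an untruncated profile the radius at which
  the tube meets any interval bound just above the myocardium level is a
  fixed ~1.6× the half-peak radius regardless of σ, which caps attainable
  DICE near 0.57; a truncated lumen with the 0.5-voxel partial-volume blur
  leaves a realistic ~1-voxel soft shoulder instead.
* **Rasterization.**  Centerlines are resampled at ≤ 0.25·min(spacing)
  arc-length steps and each voxel takes the maximum profile value over
  nearby samples (k-d tree), so curved tubes have no gaps.  Stenoses
  multiply the local radius by a factor over an arc-length span.
* **Geometry clearances.**  Tube axes keep several millimetres from every
  other contrast structure so the tubes stay disconnected both in intensity
  and in enhancement response (the positive-response zone around an axis
  extends ~1.5 effective scale radii at the largest filter scale).
* **Partial volume and noise.**  A 0.5-voxel Gaussian blur precedes
  additive Gaussian noise; all randomness flows through one explicit seed.
* **Texture.**  Optional smooth intra-tissue HU heterogeneity
  (`texture_sd_hu`, default 0; correlation length 5 mm) added to heart and
  pool.  Real myocardium is not uniform, and this heterogeneity is the
  condition under which deformable registration is identifiable away from
  tissue boundaries; the registration phantoms enable it (40 HU), while the
  growing contracts keep the flat two-level model.
* **Two-population phantom.**  For analytic sweep behaviour: a tube of
  300 ± 10 HU voxels through a myocardium held at exactly 60 HU, unblurred.
  The degenerate myocardium makes the mutation condition exact — the flood
  fires at the first v with `m − v·d ≤ 60`.  With noisy myocardium the
  upper noise tail percolates (26-neighbourhood site percolation sets in
  around 10 % occupancy) several grid steps earlier, so a noisy myocardium
  has no closed-form mutation point.
* **Atlas sets.**  Atlases are the base phantom resampled through known
  smooth warps (small affine plus low-frequency sinusoidal displacement
  fields of stated magnitude); the warps are returned so registration
  accuracy can be measured as composition error without inverting anything.

**What passing phantom tests does and does not show.**  The phantoms
exercise the full control flow and the quantitative contracts
(thresholds, erosion geometry, interval statistics, mutation placement,
registration recovery) under known ground truth.  They do not contain
real anatomy: no coronary tree topology, no motion or beam-hardening
artifacts, no intra-chamber blood contiguous with the coronary ostia, no
pathology other than geometric stenosis.  Phantom DICE ≈ 0.99 is a
recovery check, not a clinical accuracy claim.

## Problem sizes and defaults used in the shipped experiments

The default cardiac phantom is 96 × 128 × 128 at 0.4 × 0.33 × 0.33 mm
(≈ 38 × 42 × 42 mm field of view) with lumen radii 2.8 / 2.4 mm;
registration experiments use 64³ volumes at 1 mm with 3 atlases and 4-voxel
deformations.  These sizes keep every experiment reproducible on a single
CPU while leaving all algorithmic parameters at their clinical-scale
defaults (120 HU, 4 × 4 × 3 erosion, v0 = 1.0, step 0.1, 5 refinement
iterations, 256 affine iterations, 50 mm MI neighbourhood).

## Known limitations

* Registration assumes overlapping fields of view and axis-aligned grids;
  no diffeomorphic constraint or inverse consistency is enforced on the
  B-spline stage.
* The seed stage has no connected-component or shape filtering; a large
  enhanced structure above 120 HU inside the ROI would be seeded (on real
  data, chamber blood may require a positive `vesselness_floor`).
* The sweep assumes the mutation is observable within `max_v`; extremely
  uniform vessels with a tight noise floor can reach the cap first.
* Surface distances are between voxel centres; no sub-voxel surface model.
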