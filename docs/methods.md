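# Methods

## The analysis problem

After elastic registration of each subject brain to a reference atlas, the
transform `phi(x) = x + u(x)` (atlas → subject) carries all the anatomical
information the registration absorbed.  Its local volume change,
`det ∇phi(x)`, says whether the subject is locally larger or smaller than
the reference; the log Jacobian determinant (LJD) map `ln det ∇phi` is the
voxelwise carrier of that signal.  With our atlas→subject convention,
**LJD < 0 means the subject is locally smaller than the reference** —
equivalently, the voxel had to be inflated during registration to match the
atlas.  Group statistics on LJD maps (deformation-based morphometry) detect
localized hypotrophy that division-level volumetry averages away.

The package implements that chain — LJD computation, atlas-label
volumetry, voxelwise group tests, significance filtering, ROI replication
and rescue testing — together with three tabular sub-analyses from the same
study design: CRISPR cutting efficiency from fragment-analysis traces,
two-experiment differential-expression convergence, and 2^ΔCp qPCR
quantification.  Everything runs on synthetic cohorts with known ground
truth, so each stage's recovery properties are testable end to end.

## Morphometry model and numerics

**Jacobian.** `∇u` is computed by central differences scaled by the voxel
spacing (one-sided stencils at the grid boundary), and
`LJD = ln det(I + ∇u)`.  A non-positive determinant anywhere raises an
error listing the offending voxels: a folded field is a registration
failure, not a statistic.  Truncation error is second-order in the ratio of
voxel size to deformation correlation length; the volume-conservation test
bounds its practical impact below 1%.

**Volumetry.** The subject-space volume of an atlas region is
`Σ exp(LJD) · voxel_volume` over the region (change of variables), reported
both absolute (µm³) and as percent of the same subject's total brain
volume.  An independent integrator (`warped_volume`) maps a 2×-refined
sub-voxel lattice through `phi` and sums warped-cell volumes (determinant
of cell-centered edge vectors); the two routes agree below 1% on smooth
fields and serve as mutual cross-checks.

**Voxelwise tests.** The single-experiment comparison is a per-voxel
two-sided two-sample t-test, pooled-variance Student by default (Welch
optional).  Combining two experiment batches uses a per-voxel additive
two-way ANOVA (genotype + batch main effects, no interaction) with Type II
sums of squares so unbalanced designs are handled; the genotype main-effect
F and p are reported.  The implementation is a vectorised QR projection
shared across voxels; tests verify exact (1e-8) agreement with independent
per-voxel OLS fits.  Voxels with zero variance get `t = 0, p = 1` (not
NaN) and are counted; voxels outside the brain mask are forced to `p = 1`.
No voxelwise multiple-testing correction is applied — specificity comes
from the filtering cascade below, and type-I behaviour is validated on
null simulations.

**Significance filtering.** A p-value map becomes an ROI by

1. thresholding at `p < alpha` (default 0.01);
2. optionally keeping only voxels whose effect has a required sign
   (see "affected region" below);
3. the bilateral-symmetry filter: a voxel survives only if its mirror
   voxel across the midsagittal plane also passes the threshold
   (an optional tolerance radius dilates the mirrored map for approximate
   symmetry; default exact);
4. removing connected components (26-connectivity) smaller than
   `min_cluster` voxels (default 50 — a declared default, configurable,
   recorded in provenance).

Two refinements matter in practice:

- *Direction.*  A localized contraction is necessarily flanked by a shell
  of apparent dilation: tissue spanning the gap between the shrunken core
  and the unmoved surroundings is locally stretched, and with a two-sided
  test that shell is just as significant as the core.  A sign-agnostic ROI
  therefore mixes reduced and dilated voxels and its mean volume change can
  cancel to zero.  The pipeline builds the "affected region" mask from the
  reduction direction only (crispant mean below control mean).
- *Midline band.*  A cluster at the midsagittal plane is (nearly) its own
  mirror image, so for spatially correlated maps the symmetry check is
  self-confirming rather than independent evidence within about one
  correlation length of the plane.  The pipeline excludes that band
  (default 3 voxels = background correlation length / voxel size) from
  symmetry-filtered masks.  Laterally paired effects — the case the filter
  exists for — are unaffected; a genuinely medial effect would need the
  band disabled and some other control of midline false positives.

Every ROI records its full provenance (alpha, cluster size, symmetry rule,
direction, band width, connectivity).

**ROI statistics.** Replication measures a previously discovered ROI in an
independent cohort and compares groups with a two-sided pooled t-test on
ROI volume percent.  The rescue comparison is a one-way ANOVA across
control / crispant / double-crispant with error df `N − k` (39 for group
sizes 16/14/12), followed by pairwise two-sided t-tests reported
unadjusted, with a Holm-adjusted column alongside.

## Synthetic cohorts: what they emulate, and what not

The generator produces what the registration would have produced, skipping
registration itself:

- **Atlas**: an ellipsoidal brain partitioned into five divisions along the
  rostro-caudal axis, with a mirror-symmetric pair of lateral
  cerebellar-plate (LCeP) ellipsoids carved out of the cerebellar slab.
  Parametric geometry gives analytic volumes and exact mirror symmetry
  (half-integer midplane on even grids; reflection `i → 2·plane − i`).
- **Deformation** `phi = phi_bg ∘ phi_c`: a localized contraction composed
  with a smooth random background field.  The background is
  Gaussian-correlated noise (correlation length 6 µm, amplitude 0.5 µm per
  component on the default 2 µm grid), standing in for inter-individual
  anatomical variability plus registration residuals; it yields a voxelwise
  LJD SD of ≈ 0.10 and derivative SD ≈ 0.06, keeping fields comfortably
  invertible (a folded draw is regenerated at 0.7× amplitude, up to 5
  attempts, logged).  The contraction applies an *exact* linear scale `s`
  (default 0.9, i.e. a 10% linear / 27% volume deficit) on a plateau
  extending beyond the labeled LCeP, decaying smoothly (smoothstep in the
  ellipsoid quadratic form) to zero outside.  Keeping the labeled region
  and the recorded effect region strictly inside the plateau makes their
  ground-truth volume ratio exactly `s³` and the core LJD exactly `3 ln s`,
  so closed forms — not simulations — anchor the volume tests.
- **Ground truth** per subject: the effect-region mask, the contraction,
  and every division's true subject-space volume by the dense-lattice
  integrator.
- **Channels**: per-division base intensities plus smooth noise, for the
  division-level intensity table.
- **Tabular generators**: electropherograms as Gaussian peak mixtures with
  recorded area fractions (plus a crowding flag when peaks are closer than
  4σ); two per-gene DE tables with planted shared/private true genes
  (Beta(0.05, 1) p-values, sign-concordant log2FC for shared genes,
  lognormal baseMean so the ≥100 filter leaves a realistic universe);
  qPCR plates with `Cp_target = Cp_ref − log2(fold) + noise`.

Not emulated: real neuroanatomy, registration error structure correlated
with anatomy, intensity-dependent registration bias, microscope PSF, batch
effects beyond a label, overdispersed RNA-seq counts (the DE generator
makes result *tables*, not reads).  Passing tests therefore demonstrate
that the analysis recovers what the model plants under honest noise — not
that any particular real dataset would behave identically.

Group sizes in the default study configuration mirror the experimental
design (discovery 14 vs 14, replication 14 vs 17, rescue 16/14/12), and all
generators are pure functions of their seeds (per-subject seeds spawned
from the master seed).

## Expression, CRISPR and qPCR statistics

- Genes with baseMean < 100 in *either* experiment are removed (strict:
  exactly 100 is kept); BH FDR is computed within each experiment over the
  post-filter universe; significance is FDR-adjusted p strictly below 0.1.
- The convergence test is a one-sided (enrichment) Fisher exact /
  hypergeometric tail on the 2×2 membership table over the post-filter
  universe; direction agreement is counted and reported but does not enter
  the test (the construction is recorded in the output).  Tests verify the
  tail probability against exhaustive subset enumeration for small
  universes.
- Peak detection: rolling-minimum baseline (window ≫ peak width), local
  maxima above a prominence threshold, windows delimited by flanking
  minima, trapezoidal areas, sub-threshold peaks dropped.  The wildtype
  fraction assigns peaks within ±2 bp of the expected product size (the
  sequencer's own peak table could be substituted via the CSV loader).  A
  guide is efficient iff its wildtype fraction is strictly below 0.5; a
  larva is included iff any guide is efficient.
- qPCR: `ΔCp = Cp_reference − Cp_target`, relative expression `2^ΔCp`, both
  raw and normalized to the control-group mean (the design leaves the
  normalization convention open, so both are emitted), with two-sided
  t-tests between group pairs.

## Problem sizes and determinism

Simulation-based tests run at 48³ voxels (2 µm spacing): 50 null cohorts
for type-I control, 20 seeds for discovery/replication, 20 for rescue; the
acceptance script uses 20/10/10 at the same geometry.  These sizes put
binomial error bars comfortably inside the asserted bands while keeping a
full run in minutes on one core.  All stages are deterministic given the
config seed; reports embed the config hash and all thresholds.

## Known limitations

- The Jacobian is finite-difference based; fields rougher than ~2 voxels
  of correlation length would need the analytic transform (not available
  post-registration anyway).
- The symmetry filter assumes a rigid, known midplane; real registrations
  have residual midline wobble, for which the tolerance radius is provided
  but defaults to exact.
- The cluster-size default (50 voxels at 2 µm) is a declared constant, not
  estimated from the data's smoothness; a permutation-based FWER mode
  would be the principled alternative and is intentionally out of scope.
- `min_base_mean`, FDR level, and the 0.5 efficiency threshold are strict
  inequalities by convention; boundary data points are classified
  accordingly.
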