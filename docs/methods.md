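# Methods

This note documents the models and procedures implemented in `synmatch`,
the choices made where the underlying methodology left the design open,
and what the synthetic-data generators do and do not emulate.

## TMT linear model and moderated statistics (`synmatch.tmt`)

Six TMT channels fall into three groups: bait proximity labeling (TRT), a
membrane-anchored spatial-reference construct (SR), and a negative control
with a labeling reagent omitted (NC). Per protein, log2 TMT ratios follow

    log2ratio = b0 + b1·TRT + b2·SR + e,    e ~ N(0, s²)

with TRT/SR indicator variables and NC the baseline, fitted by ordinary
least squares. The bait/NC log2 fold change is `b1`; the bait/SR fold
change is the contrast `b1 − b2`. On the balanced 2/2/2 design both
contrasts have unit unscaled variance (`c'(X'X)⁻¹c = 1`) and the
coefficients reduce to group-mean differences.

**Ratio normalization.** When raw reporter intensities are supplied, each
protein's channel value becomes `log2(intensity / per-protein median
intensity)`, followed by per-channel median-centering across proteins to
remove loading differences. This is a standard ratiometric convention, not
the only possible one; tables of precomputed log2 ratios bypass it.

**Empirical-Bayes moderation.** Residual variances are shrunk toward a
prior: `s̃² = (d0·s0² + df·s²)/(d0 + df)`. The prior `(d0, s0²)` is
estimated across proteins by method of moments on log sample variances:
with `e_g = log s²_g − ψ(df_g/2) + log(df_g/2)`, solve
`ψ'(d0/2) = var(e) − mean ψ'(df_g/2)` by Newton inversion of the trigamma
function, then `s0² = exp(ē + ψ(d0/2) − log(d0/2))`. A non-positive excess
spread flags `d0 = ∞` (fully pooled variance), in which case `s0²` is the
arithmetic mean of the sample variances — the natural pooled scale, equal
to the common value when all variances are identical. Moderated t
statistics use `d0 + df` degrees of freedom (standard normal when `d0` is
infinite); `d0 = 0` recovers the ordinary OLS t exactly. A unit test
verifies exact numerical agreement (1e−8 relative) with the independent
limma implementation run through Rscript on the same matrix.

**Edge cases.** Proteins with `s² = 0` are included in moderation (the
posterior pulls them to `s0²`) but excluded from prior estimation.
Proteins left with fewer than one residual df, or with an empty design
group after missing-channel deletion, are dropped and logged. Zero
contrast estimates give t = 0, p = 1; a zero posterior variance with a
nonzero estimate reports p = 0 with a warning. Benjamini-Hochberg FDR is
applied separately per contrast (the two fold-change axes are reported
independently), via `statsmodels`, property-tested against a brute-force
step-up oracle.

## Interactome filtering (`synmatch.interactome`)

Three nested filters, applied to the moderated fits:

1. **Peptide evidence** — keep proteins identified by ≥ k unique peptides
   (default k = 2).
2. **Bait anchoring** — keep proteins with bait/NC fold change ≥ the
   bait's own (inclusive, so the bait always retains itself). This removes
   endogenously biotinylated / endogenous-peroxidase contaminants, which
   are high in every group including NC and therefore show near-zero
   bait/NC enrichment.
3. **Spatial-reference ratio** — keep proteins with strictly positive
   bait/SR fold change, removing generic membrane-proximal background
   labeled equally by the bait construct and the spatial reference.

Nesting (`step3 ⊆ step2 ⊆ step1 ⊆ detected`) is asserted on every run.
Candidates are ranked by descending bait/SR fold change; ties break by
smaller q-value then protein id so output is deterministic (the tie rule
is this package's choice — fold change alone does not order ties). The
shortlist size is a parameter (default 37), not a derived quantity.

## Volumetric indices (`synmatch.volumes`)

Single-channel volumes are segmented by threshold (Otsu's method by
default, explicit override available), with connected components below a
minimum size removed (26-connectivity by default, matching the common
3D-object-counter convention). The indices are voxel-count ratios on a
common grid, so voxel size — including anisotropic voxel size — cancels:

* match index = |axon ∩ dendrite| / |dendrite|
* mismatch index = |axon ∩ dendrite| / |axon|
* mistarget index = Σ intensity in glomerulus A / Σ intensity in A ∪ B
  (masks must be disjoint)

Whether each channel should be thresholded independently or jointly is not
dictated by the method; the implementation thresholds independently by
default and accepts a shared explicit threshold.

## Axon morphometry (`synmatch.morpho`)

SWC traces (1-based ids, parent −1 at the root, μm units, radii required)
are parsed into rooted trees with full validation (single root,
connectivity, positive radii).

* **Stem axon** — "thickest path" is operationalized as the root-to-leaf
  path maximizing the path-length-weighted mean radius; ties go to the
  longer path, then the lexicographically smaller leaf id. This is robust
  to local radius noise and deterministic; an exhaustive path-enumeration
  oracle confirms it on random trees.
* **Entry and end** — entry is the first stem node (root→tip) inside the
  antennal-lobe region; the end is the stem node geodesically farthest
  *distal* to the entry (a stem touching the region only at its tip
  degenerates to entry = end, length 0). Stem length is geodesic arc
  length between them.
* **Stage** — stem length < 100 μm → stage 1; 100–170 μm (closed
  interval) → stage 2; > 170 μm → stage 3. Closing the middle interval
  makes the three intervals a partition.
* **Primary branches** — every collateral subtree off the stem yields one
  record: position normalized to the entry=0/end=1 axis (branch points
  outside that span are excluded and logged, not clamped); PN contact iff
  any subtree node lies inside the PN dendrite region (point-cloud
  regions carry a contact tolerance ε, default 2 μm; voxel-mask regions
  use exact membership); multifurcated iff the subtree contains an
  internal branch point, with `n_secondary` counting the split events;
  laterality from an optional midline plane, relative to the entry side.
* **Summaries** — branch density (primaries per μm of stem), contacting
  fraction over primaries, contacting fraction of multifurcated
  primaries, secondary count on contacting primaries, and a position
  histogram on [0, 1] (default 20 bins). Fractions with empty
  denominators are NaN.
* **Group comparisons** — one-way ANOVA with Tukey HSD (with Shapiro-Wilk
  and Brown-Forsythe gates reported), pairwise 2×2 chi-squared without
  continuity correction with Bonferroni correction, or Kruskal-Wallis
  with pairwise Mann-Whitney U and Bonferroni correction.

## F-actin profiling (`synmatch.factin`)

Marker intensity is sampled at every trace node as the mean over a sphere
of radius 1 voxel defined in voxel index space (matching the behavior of
the plot-profile tool the convention comes from; on anisotropic grids the
sphere is anisotropic in physical space). Out-of-bounds nodes are flagged
missing and excluded from both normalization extremes and densities.
Samples are min-max normalized per axon (max node → 1, min node → 0), so
densities are invariant to affine transforms of the raw field.

Segment density is the trapezoidal integral of normalized intensity over
arc length divided by segment length — an arc-length-weighted mean,
invariant to trace resampling, for which a segment's density is exactly
the length-weighted mean of its halves. A node-sum/length variant (which
depends on node spacing) is available behind a flag. "Total normalized
intensity / length" is ambiguous between the two readings; the integral
form is the default precisely because of the resampling invariance.

Comparisons on stage-3 axons: PN-contacting vs non-contacting whole-branch
densities by Mann-Whitney U; within contacting primary branches, the
PN-contacting "(+)" vs non-contacting "(−)" subsegments by paired t, one
pair per branch. Subsegment membership is decided per edge by its
midpoint. Zero-variance positive paired differences are degenerate and
reported as p → 0 with a warning.

## Synthetic data (`synmatch.simulate`)

All generators are deterministic given their seed.

**TMT tables.** Default scenario: 2000 proteins — 50 interactors
(fc_NC = 3, fc_SR = 2), 200 membrane-background (fc_NC = 3, fc_SR = 0),
100 endogenously biotinylated contaminants (level 2 in all groups, so
fc_NC = 0), the rest null — plus a bait row (fc_NC = 1.5, fc_SR = 1),
with i.i.d. Gaussian channel noise (sd 0.25 log2 units). Planted classes
draw unique-peptide counts ≥ 2; null proteins can have a single peptide,
so the peptide filter has work to do. Gaussian noise on log2 ratios is
the minimal standard choice; real reporter-ion data have
intensity-dependent variance and correlated missingness this generator
does not emulate, so recovery tests demonstrate correctness of the
filtering logic, not robustness to real acquisition artifacts.

**Glomerular volumes.** Two congruent ellipsoids on a 64³ grid; the axon
ellipsoid is shifted along one axis with the shift solved by bisection so
the voxelized overlap fraction |A∩D|/|D| hits the programmed value
(typically within ±0.005). Truth indices come from the noiseless masks;
emitted volumes are intensity·mask + Gaussian noise. No PSF or photon
statistics are simulated.

**Axons with fields.** The stem is a gently curved polyline of
stage-consistent arc length (entry-to-tip length drawn from 40–95 /
105–165 / 180–240 μm for stages 1/2/3), preceded by a 20 μm pre-entry
run; node spacing 2 μm; stem radius ≈ 1 μm vs branch radii ≈ 0.3 μm so
the stem is unambiguously the thickest path. Primary branch counts follow
per-stage densities (0.12 / 0.08 / 0.05 per μm), positions per-stage
distributions (uniform at stage 1, increasingly PN-peaked beta
distributions later). Each branch is PN-contacting with probability
`contact_probability` (default 0.7) and its geometry realizes the label:
contacting branches are steered through a random interior point of the PN
sphere (radius 12 μm, offset 16 μm laterally from the stem), non-contacting
branches head away from it. Multifurcated branches (probability 0.3) get a
secondary branchlet at an internal node.

The intensity field paints every neurite as a ~1 μm tube (flat value 0.5,
max-combined where structures overlap) on a 1 μm grid, adds
`factin_boost` (default 0.3) inside PN-contact zones, applies a light
Gaussian blur (σ = 0.3 voxels), and adds i.i.d. voxel noise (sd 0.08).
Painting extends 4 μm past every tip so sampled nodes always sit in a
locally tube-like neighborhood. These choices matter for the null
behavior of the within-branch comparison: flat max-combine painting,
per-branch target spread, fine voxels, and tip overpainting remove the
geometric (+)/(−) asymmetries (tube crowding near the PN sphere, blur
dimming at tips) that coarser or blurrier fields introduce, so that with
`factin_boost = 0` the paired-t p-value is genuinely uniform. The
acceptance suite verifies this calibration empirically (type-I error at
α = 0.05 within 0.05 ± 0.02 over 1000 simulated axons). Real image stacks
have structured background, a PSF, and intensity falloff the generator
does not model.

## Problem sizes and numerics

Default test and acceptance runs use: 2000-protein TMT tables; 64³ volume
grids; 30–40 simulated axons for recovery rates and 1000 for the null
calibration; 200 random trees (≤ 50 nodes) for the stem oracle; 100
random 32³ mask pairs for the voxel-loop oracle. These sizes give stable
Monte-Carlo estimates (binomial s.e. ≤ 0.007 on the calibration rate)
while the whole suite runs in about a minute. Trigamma inversion uses
Newton iteration to 1e−10 relative tolerance with asymptotic endpoints;
ellipsoid-shift bisection runs 60 iterations. Degenerate inputs
(constant profiles, empty masks, zero-length stems, rank-deficient
designs) raise informative errors rather than propagating NaNs.

## Known limitations

* The ratio-reference convention (per-protein median, then per-channel
  centering) is one standard choice among several; results on real tables
  depend on which convention produced them.
* Isotope-impurity correction, peptide-to-protein rollup, and
  reporter-ion extraction are out of scope; inputs are protein-level.
* Region definitions (antennal lobe, PN dendrites, midline) are consumed,
  not inferred from images.
* The `compare_groups` chi-squared path operates on per-group
  (successes, totals) contingency counts and does not model per-axon
  clustering.
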