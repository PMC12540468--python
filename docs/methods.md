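# Methods

## Problem setting

Spatial transcriptomics (ST) and spatial metabolomics (MSI) are acquired
from adjacent tissue sections on separate instruments. ST spots sit on a
hexagonal array (spot diameter 55 µm, pitch 100 µm); MSI pixels sit on a
square raster (step 100 µm). Section transfer introduces an unknown
scale, rotation and translation between the two coordinate systems, so
attaching metabolite intensities to spots requires an explicit planar
similarity registration. `spotmatch` estimates that registration from
manually paired landmarks and carries the matched data through
spot-level aggregation, two-group differential statistics, cell-type
designation and pseudotime trend classification.

## Coordinate conversion

Spot array indices use the parity-offset hex encoding of the Visium
`tissue_positions.csv` dialect: within a row, column indices share
parity and neighbours differ by 2. Conversion to micrometres is

    x = (col/2 + 0.5) · pitch        y = row · sqrt(3/4) · pitch

so same-row neighbours are exactly one pitch apart and the six hex
neighbours of an interior spot all lie at one pitch. The +0.5 offset
shifts all spots uniformly and cancels in registration; it is kept for
fidelity to the index convention. Indices are 0-based; the y-axis
follows increasing row index with no image flip (a mirrored section is
detected from landmark chirality and is an error unless reflection is
explicitly allowed). MSI pixels convert as `x = i·step`, `y = j·step`.
The spot diameter is metadata only; it does not enter the conversion.

## Similarity-transform estimation

Given n ≥ 6 landmark pairs (spot barcode ↔ MSI pixel), all C(n,2)
unordered pairs contribute:

- **Scale**: the ratio of ST to MSI pairwise distances. Ratios are
  filtered by a median ± 3·MAD rule (configurable: 1.5·IQR fences, or
  none) and the surviving ratios are averaged. The MAD rule is
  parameter-light, has a 50 % breakdown point, and with ≤ 20 % grossly
  displaced landmarks restores the scale to within 1 % (verified over
  seeded replicates).
- **Rotation**: per-pair orientation difference computed with the
  two-argument arctangent. The one-argument ratio form cannot
  distinguish opposite quadrants and aliases rotations beyond ±90°, so
  the quadrant-aware form is used deliberately. Per-pair angles are
  combined by a circular mean on unit vectors weighted by the pair's
  baseline length: angle noise for a jittered pair scales as
  jitter/distance, so short baselines carry little information. The
  circular (not arithmetic) mean is essential near the ±180° wrap. A
  weighted circular standard deviation above 15° (configurable) aborts
  the fit as inconsistent with a rigid rotation. Rotations whose
  magnitude strictly exceeds 5° set a flag; by default the estimated
  rotation is applied regardless of the flag (`rotation_mode="always"`),
  because silently dropping small rotations biases pixel matching. A
  `"threshold"` mode applying rotation only above 5° is provided.
- **Translation**: the scaled-and-rotated MSI landmark centroid is
  aligned with the ST landmark centroid: `p' = s·R(θ)(p − c_MSI) + c_ST`.

Sign convention: the stored angle rotates MSI coordinates into the ST
frame, counter-clockwise positive; per-pair angles are measured MSI
minus ST and negated when the transform is assembled.

A closed-form least-squares similarity fit (Umeyama SVD estimator)
serves as an independent oracle: on noise-free landmarks the two
estimators agree to 1e-9; on jittered landmarks the oracle's residual is
never larger, by least-squares optimality. The oracle validates the
pairwise method and is never used as the production path.

## Pixel-to-spot integration

Pixel spectra are divided by their total ion count (TIC); zero-TIC
pixels are excluded with a warning (configurable to error). Each
transformed pixel is assigned to its nearest spot if the distance is at
most the matching radius; the default radius of 50 µm (half the pitch)
tiles the plane into spot cells so a 100 µm raster puts about one pixel
in nearly every covered spot. The spot radius (27.5 µm) would leave most
spots empty and is deliberately not the default. Exact-distance ties
(within 1e-6 µm) go to the lexicographically smallest barcode for
determinism. Assigned pixels are averaged per spot (median
configurable); assignment is a partition (assigned + unassigned = total)
and aggregation preserves pixel-count-weighted mass to 1e-9.

Cell-type designation from external deconvolution proportions applies
the literal rule: the top type names the spot only when its proportion
strictly exceeds 0.70; otherwise the second-largest type is chosen. The
else-branch is surprising but is implemented verbatim; a conventional
`dominant` (arg-max) mode exists because downstream users will expect
it. Within-row ties rank by proportion, then label, making the output
independent of column order.

## OPLS-DA, VIP and significance calling

The two-group model is the orthogonal-signal-corrected NIPALS scheme:
X is column-centred and unit-variance scaled, y is the ±1 group coding,
and each orthogonal component removes from X the part of its loading
orthogonal to the predictive weights before the final one-component PLS
fit. Defaults: one orthogonal component; 7-fold stratified
cross-validation for Q² (chemometrics convention; every fold keeps both
groups represented); fixed seed for fold assignment. R²X is the variance
of X captured by predictive plus orthogonal components; R²Y the fitted
variance of y; Q² = 1 − PRESS/SS(y) with test observations filtered by
the training fold's orthogonal components before projection.

VIP over the single predictive component reduces to `sqrt(p)·|w_j|`
with unit-norm weights, so mean VIP² = 1 by construction (and VIP ≡ 1
when p = 1). Permutation testing refits the full pipeline under label
permutation (default 200); on genuine signal the permuted Q²
distribution centres below zero, and the empirical p is
`(1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1)`.

The univariate p-value is a two-sided Welch t-test on `log(x + ε)` with
ε set to half the minimum positive intensity (heteroscedastic positive
intensities; Wilcoxon rank-sum available). Fold change is the log2 ratio
of raw group means. Significance is the strict conjunction VIP > 1 and
p < 0.05, with no multiple-testing correction by default
(Benjamini–Hochberg behind a flag). Zero-variance metabolites are
reported with a note and never called. Note that the conjunction's
type-I level on exchangeable data is essentially the t-test's nominal
5 %: under an independent-metabolite null the VIP > 1 condition removes
almost none of the p < 0.05 variables, so the rule should be read as
"nominal 5 % level plus a relevance filter", not as a conservative
correction.

## Pseudotime trends

Branch assignments and pseudotime come from an external trajectory tool
(e.g. Monocle on the trophoblast lineage: villous cytotrophoblast root,
syncytiotrophoblast branch, extravillous branch). Spots are projected
onto the two root-to-tip paths, prebranch spots prepended to both, and
each metabolite is classified per path by Spearman correlation with
pseudotime: increasing (ρ ≥ 0.3, p < 0.05), decreasing (ρ ≤ −0.3,
p < 0.05), else unchanged. Rank-based classification is invariant to
monotone re-parameterisation of pseudotime, and reversing pseudotime
flips the calls. The smoothed profile is a mean over equal-count
pseudotime bins (default 20). The threshold/binning rule is this
package's definition; published density/line plots of such dynamics are
treated as qualitative pattern classes only.

## Synthetic generator

The generator produces paired sections with full ground truth under the
package's default study conditions: a 20×20 hex grid at 100 µm pitch, a
100 µm MSI raster covering the same virtual tissue through the inverse
of a planted similarity transform, m/z values inside the 70–1200 Da
instrument range, and log-normal intensities (MSI ion counts are
positive and right-skewed) structured by a two-territory region map
("villous"-like vs "basal-plate"-like) split along x. Landmarks are
chosen by farthest-point sampling for even spread; jitter and a gross
outlier fraction (displacement 500 µm) are configurable, defaulting to
clean landmarks. The group study plants 5 informative metabolites of 50
at a 2 SD additive log-scale effect with 30 observations per group; the
branch study uses 30 prebranch plus 40 spots per branch (70 per path)
with planted monotone log-slopes sized for |ρ| ≥ 0.5. Everything is
driven by a mandatory seed; changing the seed changes the data but not
the truth structure.

What the generator does **not** emulate: mass-spectral structure
(isotopes, adducts, peak shape), spatial autocorrelation of intensities
within a region, correlated metabolite panels, section-to-section
biological drift, or segmentation/deconvolution/trajectory inference
themselves (their outputs are inputs here). Passing tests therefore
demonstrate correctness of the registration arithmetic, the estimators'
robustness model, and the statistical machinery under idealised
conditions — not performance on real tissue.

## Numerical choices and edge cases

- Angles live in (−180°, 180°]; all averaging is circular.
- The 5° flag and the VIP/p thresholds are strict inequalities
  (5 is not > 5; VIP = 1.0 is not significant; a 0.70 proportion does
  not exceed 70 %).
- Landmark sets must be rank-2 in both frames; collinear or duplicate
  landmarks, coincident pair points, and mirrored configurations raise
  typed errors naming the offending items.
- Constant metabolite columns are dropped (warning) before OPLS-DA;
  all-rejected ratio sets and sub-minimum landmark counts are errors
  advising more landmarks.
- Problem sizes in the test-suite Monte-Carlo loops (100 seeded
  replicates; 200 permutations; 20×20 grids) are chosen to make the
  checked proportions stable at the asserted margins while keeping the
  default suite fast.

## Known limitations

- Only planar similarity (+ optional reflection) transforms: no shear,
  no non-rigid warping, no intensity-based refinement.
- Landmarks are supplied, not detected; no fiducial or H&E processing.
- One predictive OPLS component (binary designs); multi-class contrasts
  are out of scope.
- The significance rule's level control relies on the univariate test;
  with correlated metabolites the VIP filter interacts with that level
  in ways the independent-null analysis here does not cover.
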