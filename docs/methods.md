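# Methods

## Cohort and derived variables

The registry is a per-patient CSV with survival days (from surgery/biopsy
to death or censoring), a death indicator, age, sex, dichotomized
Karnofsky Performance Status (≥ 70 = functionally independent), a
biopsy-only flag, a radiochemotherapy flag, the preoperative tumor volume
(contrast-enhancing rim plus necrotic core, mL) and the post-operative
residual contrast-enhancing volume (mL, may be missing).

Derivations:

* **OS groups.** Deceased patients: short (< 6 months), medium (6–24
  months, closed on both ends), long (> 24 months). Months are converted
  as round(365.25·k/12): 183 and 731 days; both thresholds are
  configurable. Censored patients can only be classed long (follow-up
  > 731 days); otherwise they are unassignable and excluded from the maps
  with a logged warning. The 6–24-month window being closed at both ends
  is a convention choice — the day-resolution boundary cases are rare and
  the choice is documented here precisely because the interval endpoints
  are ambiguous in prose descriptions.
* **Residual tumor volume (RTV).** Contrast-enhancing components only in
  resected patients; equal to the full preoperative volume in biopsy-only
  patients. Resected patients without a post-operative volume are flagged
  and excluded from RTV-using models only.
* **RTV bins.** (0,5], (5,10], (10,15], (15,20], (20,∞) mL, 0 included in
  the first bin — the half-open-right reading of the printed labels
  "0–5 mL" / "5.1–10 mL".

## Statistical maps

All masks must share one grid (shape and affine within 1e-4 mm; inputs
with non-binary values are binarized at 0.5, which is robust to
interpolation artifacts from registration). Maps are stored as NIfTI with
a JSON provenance sidecar (groups, group sizes, seed, permutation count,
alpha, epsilon, analysis-domain size); counts are int16, significance
masks int8, everything else float32, so write/load round trips are
bitwise.

**Odds and log-OR.** Group odds per voxel are k/(n−k) with the epsilon
substitution applied to the count itself: k = 0 → ε/(n−ε) and k = n →
(n−ε)/ε, with ε = 1e-6. Substituting in the denominator as well preserves
the antisymmetry log-OR(A,B) = −log-OR(B,A) exactly; the k = n branch (a
voxel where every patient of a group has tumor, possible in small groups)
is logged as a warning. As ε → 0 the substituted values converge to the
plain odds wherever 0 < k < n.

**Fisher exact tests.** Each pairwise comparison tests, per voxel, the
2×2 table (group × tumor presence) with the two-sided Fisher exact test:
the sum of hypergeometric probabilities of all tables with the same
margins whose probability does not exceed the observed table's, with a
1e-7 relative tolerance so floating-point ties are included. Because
group sizes are fixed across voxels, all p-values come from one
(nA+1)×(nB+1) lookup table, making the observed pass and every
permutation an O(voxels) gather.

**Analysis domain.** Odds and tests are only meaningful where tumors
occur: each comparison is evaluated on the voxels covered by at least one
patient of the two groups compared; outside, maps are NaN. An explicit
domain mask can be supplied to widen (e.g. whole-cohort coverage) or
narrow the region.

**Permutation adjustment.** Group labels of the nA+nB patients are
randomly reassigned (group sizes preserved) n_perm = 2000 times; each
permutation yields a null p-value map via the lookup. The adjusted
p-value at a voxel is the proportion of its own null p-values **at or
below** the observed one. Counting ties is deliberate and is the one
place this implementation departs from the strict "proportion smaller
than" phrasing: the voxel-wise null is discrete, and at sparsely covered
voxels its support is tiny, so under the strict rule every voxel whose
observed p attains the minimum of its own null support gets adjusted
p = 0 — measured on label-permuted null cohorts this flags ~8% of domain
voxels at α = 0.01, an order of magnitude above nominal, concentrated in
a shell of low-coverage voxels. With tie counting the flagged fraction is
~0.3% (see the acceptance suite). The strict rule remains available via
`PermutationConfig(count_ties=False)`, and a (b+1)/(n_perm+1) smoothed
estimator via `smoothed=True`.

Permutations are drawn from counter-based Philox streams keyed by the
comparison seed with the permutation index in a high counter word, so
results are reproducible bit-for-bit and independent of traversal or
chunking order. By default labels are reshuffled within each pair
("pairwise" scheme — each comparison's null concerns those two groups); a
joint reshuffle of all three group labels is available as
`scheme="global"`.

**Significance.** Voxels with adjusted p ≤ 0.01 (boundary included) are
set to 1, the rest (including NaN domain) to 0; the mask is applied to
the log-OR map so only significant voxels remain visible.

## Tumor centrality (TVTB)

TVTB is the shortest Euclidean distance, in cm, from a reference world
point (center of the third ventricle, supplied in config — no atlas
parcellation is performed) to the tumor border: mask voxels with at least
one 6-connected neighbor outside the mask, volume boundary included.
Distances are measured to voxel centers, not sub-voxel surfaces — binary
masks do not justify a surface model — so the error is bounded by half
the voxel diagonal. A reference point falling inside the tumor returns 0
rather than a signed distance. The border restriction is exact: for an
exterior point the nearest mask-voxel center is always a border voxel
(verified against brute force over all voxels in the test suite). The
border of the full mask (enhancing rim plus necrosis) is used; in a
rim-enhancing tumor this coincides with the outer enhancing border.

## Regression models

* **Cox PH (overall survival).** Efron approximation for day-resolution
  ties; candidates screened univariably at p ≤ 0.1; the age × TVTB
  interaction is tested inside the multivariable model and retained at
  p ≤ 0.01 (other interactions configurable, none on by default).
  Complete-case analysis per model with exclusions recorded (patients
  missing RTV are dropped only from RTV-using models). Non-convergence
  raises a diagnostic error carrying the design-matrix condition number;
  constant covariates are rejected by name.
* **Combined hazard ratio.** With the interaction, the per-cm HR of TVTB
  at age a is HR_tvtb · HR_interaction^a, exactly HR_tvtb at a = 0 and
  monotone decreasing in age when the interaction HR is below 1.
* **Binomial logistic** (biopsy-only; radiochemotherapy) via maximum
  likelihood; (quasi-)separation is detected (constant outcome, unbounded
  standard errors) and raised as an error rather than reported.
* **Proportional-odds model** on the five ordered RTV bins, resected
  patients only; empty bins produce a warning, fewer than two occupied
  bins an error.

All confidence intervals are 95% Wald intervals on the log scale, so
HR = exp(coef) holds identically and CIs are multiplicative.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, on a 32³ grid
at 4 mm (a "fullres" 91×109×91 @ 2 mm profile exists but is not used in
tests):

* **Anatomy.** Tumors are ellipsoids with per-axis radii uniform in
  8–30 mm, centered uniformly inside a brain ellipsoid of semi-axes
  (54, 60, 54) mm and clipped to it. The defaults give a median tumor
  volume of ~25 mL and a tumor/brain volume ratio of ~0.03, matching the
  coverage regime of a ~34 mL median tumor in a real brain. Preoperative
  volume is voxel count × voxel volume by construction.
* **Planted effect.** A spherical region R (default radius 20 mm at the
  third-ventricle reference point): tumors overlapping R raise the
  patient's short-OS probability from 0.15 to 0.6; the remaining mass is
  split 75/25 between medium and long. Survival days are then drawn
  within the assigned group's interval (long-survivor tails are
  exponential with mean 400 days past the 24-month mark, administratively
  censored at day 1400, so roughly a fifth of long survivors are
  censored and no patient is censored before 24 months).
* **Hazard mode.** Alternatively survival is exponential with log-hazard
  linear in age, TVTB and age × TVTB (baseline anchored to a 374-day
  median at typical covariates) for parameter-recovery studies; OS groups
  then follow from the sampled times.
* **Covariates.** Age ~ N(65, 12²) truncated to [18, 95]; sex Bernoulli
  (61% male); KPS ≥ 70 with logit 1.0 − 0.06·(age − 65); biopsy-only with
  logit −0.2 − 0.5·TVTB (central tumors get biopsied); radiochemotherapy
  with logit 1.0 + 0.3·TVTB − 0.05·(age − 65); residual volume =
  preoperative volume × Beta(0.8, 8) fraction for resected patients
  (median residual ~1.6 mL), equal to the preoperative volume for
  biopsy-only patients.
* **Null cohorts.** `generate_null_cohort` permutes a fixed label vector
  (52/122/41 by default) independently of the masks, for type-I-error
  suites.

Everything is deterministic given the config seed; the returned truth
record carries the region, effect size, overlap flags, TVTB values, group
labels and hazard coefficients for recovery tests.

What the generator does **not** emulate: MRI intensities, registration
error, infiltrative margins, multifocal disease, non-ellipsoidal growth,
spatially varying tumor incidence. Passing tests therefore demonstrate
the statistical machinery under the stated generative model, not
segmentation or registration robustness on real images.

## Acceptance-suite problem sizes

The behavioral suites use sizes chosen to make each property measurable:

* Fisher exactness: exhaustive integer-arithmetic enumeration of every
  table with nA + nB ≤ 30.
* Permutation correctness: a 4-voxel, 8-patient instance where all 70
  label assignments can be enumerated; Monte-Carlo at n_perm = 2000 must
  agree within 3 binomial standard errors.
* Null calibration: 20 seeded null cohorts (215 patients, 52/122/41),
  three comparisons each at n_perm = 500 (scaled down from 2000; the
  flagged-fraction estimate only needs resolution well below 0.01), mean
  flagged fraction ≤ 0.03.
* Planted-region recovery: 20 seeds at n = 215, n_perm = 500, with tumor
  radii 22–32 mm and region radius 8 mm. This scenario was designed by a
  power analysis of the effect model: at the realistic default coverage
  (~6 patients per voxel inside R) the per-voxel Fisher test is
  underpowered at adjusted p ≤ 0.01 regardless of implementation, so the
  recovery suite uses a geometry where tumors overlapping R nearly all
  cover it (~45 overlapping patients, per-voxel coverage ~15) while the
  global short-OS fraction stays low. Sensitivity is measured on R ∩
  domain; false positives outside R dilated by the maximum tumor radius
  (the distance to which a genuinely associated tumor can extend).
* Cox recovery: 100 replicates at n = 2000 with planted coefficients
  (0.079 /year, 0.6 /cm, −0.012 /(year·cm), on the scale of the
  clinical estimates); each coefficient must fall inside its fitted 95%
  CI in ≥ 90 replicates.

## Known limitations

* The epsilon-substituted log-OR at voxels with a zero count is
  essentially a clipped value (~±16 at ε = 1e-6); its magnitude is not
  interpretable, only its sign.
* The permutation adjustment controls the per-voxel error rate against
  the label-permutation null; it is not a family-wise or FDR correction
  across voxels, and no cluster-extent or TFCE-style inference is
  offered.
* Adjusted p-values have Monte-Carlo resolution 1/n_perm; at the default
  α = 0.01 use n_perm ≥ 500.
* The ordered-logistic stage assumes proportional odds across bin
  thresholds; no test of that assumption is run.
* Cox diagnostics are limited; proportional hazards is assumed.
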