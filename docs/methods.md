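# Methods

## Problem and scope

`petquant` quantifies whole-body tumour burden on FDG-PET: given an SUV
volume and per-lesion annotations (bounding box, site label, optional
seed), it segments each lesion with four SUV-threshold rules, computes
per-lesion metabolic tumour volume (MTV), SUVmean, SUVmax and total
lesion glycolysis (TLG = MTV x SUVmean), sums them to whole-body totals
(WBMTV, WBTLG), and feeds those biomarkers into a prognostic workflow
(ROC cutoff, Kaplan-Meier / log-rank, multivariate Cox). A synthetic
module generates digital phantoms and survival cohorts so that every
stage can be validated without clinical data.

## SUV and image conventions

SUV is the body-weight variant: `SUV = C[kBq/mL] * weight[kg] /
dose[MBq]`, dimensionless under the 1 kg ~ 1000 mL tissue convention.
Decay correction is assumed done upstream; the acquisition metadata
records the flag but does not act on it. Voxel arrays are indexed
(x, y, z) with per-axis spacing in mm; voxel indices are 0-based and
bounding boxes half-open `[lo, hi)`. DICOM slice order is resolved by
sorting on the projection of the image position onto the slice normal;
series mixing orientations are rejected rather than resampled.

## Threshold rules

All four rules mark voxels with `SUV > threshold` (strict inequality,
one convention for all four):

| rule  | threshold                          |
|-------|------------------------------------|
| Th2.5 | 2.5 (absolute)                     |
| Th20  | 0.20 x SUVmax                      |
| Th40  | 0.40 x SUVmax                      |
| Thbgd | SUVbgd + 0.20 x (SUVmax - SUVbgd)  |

SUVmax is read at the seed voxel — the annotated seed if given, else
the hottest voxel in the bounding box (ties broken by lowest linear
index, for determinism). The strict `>` makes the degenerate case
SUVbgd = SUVmax yield an empty segmentation rather than an arbitrary
one; when SUVbgd exceeds SUVmax a `ThresholdWarning` is raised and the
segmentation is empty.

## Background estimation (Thbgd)

SUVbgd is the mean of the per-region maximum SUV over ten spherical
regions (default radius 2 voxels) placed at seeded-random,
non-overlapping centres in a shell 1–5 voxels outside the lesion
bounding box. Candidate centres are rejection-sampled: they must fall
inside the image with the whole sphere, must not intersect any lesion's
bounding box (so adjacent lesions never contaminate the background),
and must not overlap an already-placed region. Region count, radius
and shell are configurable; the estimate is deterministic given the
RNG seed. If the shell cannot host ten regions the estimator fails
loudly, naming the lesion.

Using each region's *maximum* (not mean) as the per-region statistic
is a deliberate reading of the background definition as "the mean of
the regions' SUVmax values"; it biases SUVbgd slightly upward under
noise, which makes the background-relative threshold conservative.

## Region growing and the leak rule

The mask is the 6-connected (face-adjacent) component of
super-threshold voxels containing the seed, computed inside the
annotation bounding box dilated by a leak margin (default 3 voxels)
and clipped to the image. Component extraction uses
`scipy.ndimage.label`; the test suite cross-checks it against a
hand-written breadth-first flood fill on exhaustive small grids.

A lesion is *unsegmentable* in two ways: the seed itself is not above
threshold (status `EMPTY`), or the grown component touches the outer
face of the dilated box (status `LEAKED`) — the operational definition
of "merged with surrounding background". Only `DETECTED` lesions count
toward detection rates and contribute to WBMTV/WBTLG; unsegmentable
lesions carry zero MTV/TLG and an `excluded` flag. (Whether excluded
lesions should instead be imputed is a sensitivity question; exclusion
is the only deterministic default and is what the aggregation
implements.)

6-connectivity is the conservative choice for region growing — with
26-connectivity diagonal noise voxels chain more easily, inflating
masks and leak rates.

## Metrics

MTV = voxel count x voxel volume (cm^3) — identical, for a voxelised
mask, to summing per-slice area x slice thickness. SUVmean is the
arithmetic mean over the mask, TLG = MTV x SUVmean exactly (asserted
to machine precision in tests). Whole-body totals sum over detected
lesions; the patient SUVmax is the maximum over all lesions, detected
or not, since it is read at the seed rather than from the mask.

## The digital phantom

The phantom is background + sharp spheres at the lesion peak SUV,
convolved with an isotropic Gaussian (FWHM default 6 mm) as a
partial-volume surrogate, plus additive Gaussian noise (default SD
0.05 SUV) clipped at zero. Lesions must be mutually disjoint so that
per-lesion ground truth (analytic 4/3 pi r^3 and the voxelised volume)
stays well defined. All randomness flows from a single seed;
regeneration is bit-identical.

What the phantom does *not* model: anatomy and heterogeneous
physiological uptake, Poisson noise in projection space,
reconstruction artefacts, respiratory motion. Passing phantom tests
therefore demonstrates correctness of the segmentation arithmetic and
the qualitative threshold behaviours (absolute-rule blindness below
2.5, relative-rule leakage at low contrast, background-rule
robustness), not clinical accuracy.

A property worth knowing when reading the phantom results: under blur,
the 40%-of-SUVmax contour always lies outside the true boundary when
the background is positive (the blurred edge value is
bg + (peak-bg)/2, which exceeds 0.4 x peak for any bg >= 0), so Th40
systematically overestimates volume, mildly at high contrast (~6–10%
at 15:1 for radii >= 10 mm) and grossly at low contrast (~50% at 4:1).
This is the same mechanism that makes fraction-of-SUVmax rules fail on
low-uptake lesions.

## The simulated cohort

Each patient gets: age ~ Normal(46, 12) clipped to 17–75; gender
Bernoulli (76.4% male); treatment in three ordered levels
(radiotherapy only / radiotherapy + chemotherapy / any surgery,
probabilities 0.405 / 0.540 / 0.055); lesion count 1 + Poisson(1.6);
and log-normal tumour burden — WBTLG with arithmetic mean 88.6 and SD
127.9, WBMTV with mean 15.2 and SD 21.1, correlated through a shared
latent normal (rho = 0.9). The log-normal reproduces the strong
mean >> median right-skew characteristic of whole-body burden in
post-therapy cohorts.

Overall survival is exponential with hazard
`h0 * exp(beta * WBTLG)` (defaults h0 = 0.004/month, beta = 0.003 per
WBTLG unit — the order of magnitude implied by a hazard ratio of
~1.002–1.003 per unit); censoring is an independent exponential
(default 0.01/month), optionally truncated at a maximum follow-up.
Disease-free survival uses the same linear predictor at 1.5 x the
baseline hazard, drawn independently — DFS is not coupled to the OS
draw, which is adequate for calibration studies but means joint
OS/DFS statements should not be read off one simulated cohort.

## Statistical choices

- **Detection comparison**: global 4x2 chi-square (no continuity
  correction) on detected-vs-not by method; all pairwise 2x2
  comparisons, switching to Fisher's exact test whenever an expected
  cell count is below 5. P-values are raw; no multiplicity correction
  anywhere in the package.
- **ROC cutoff**: AUC by the rank/Mann-Whitney formulation with tie
  correction; candidate cutoffs at midpoints between consecutive
  distinct values; the default criterion is Youden's J with ties
  broken toward the lower cutoff (criterion `closest` — minimum
  distance to the (0,1) corner — is available).
- **Stratification**: patients with biomarker `>= cutoff` form the
  high-risk group; survival at the horizon (default 60 months) is read
  from the product-limit step function; groups are compared with the
  standard two-group log-rank test.
- **Cox model**: partial likelihood with Efron tie handling (the
  lifelines default) on seven covariates — age, gender, treatment
  (ordinal), lesion count, SUVmax, WBMTV, WBTLG; hazard ratios with
  Wald 95% CIs. Non-convergence and separation surface as explicit
  errors, never as silent output. Survival times are assumed already
  referenced to treatment start; the package does no date arithmetic.

## Calibration results and problem sizes

The calibration studies run at sizes chosen to bound Monte-Carlo error
while staying desk-scale: the log-rank type-I error uses 2000 null
replicates of n = 200 (binomial SE ~ 0.005 at the nominal 0.05), and
Cox recovery uses 300 replicates of n = 2000 with true beta = 0.003
(coverage SE ~ 0.013). Observed values — rejection rate ~ 0.047–0.049,
coefficient bias ~ 1%, CI coverage ~ 0.93–0.96 — are recomputed, not
quoted, by `scripts/acceptance.py` and the acceptance tests.

## Numerical details and degenerate inputs

- Printed percentages in the published lesion tables truncate rather
  than round to one decimal (521/576 = 90.45% appears as 90.4);
  comparisons against those tables truncate accordingly.
- An empty annotation list, a zero-lesion phantom, and a lesion whose
  peak falls below every threshold are all valid inputs with defined
  outputs (empty list, uniform background image, `EMPTY` status).
- An all-censored cohort or single-class ROC outcome is rejected up
  front with an explicit error.
- NIfTI round-trips preserve spacing exactly and voxels to float32
  precision (volumes are stored as float32).

## Known limitations

- The leak rule depends on the annotation bounding box; a box drawn
  far too large can hide a true leak, one drawn too tight can flag a
  valid lesion. The margin is configurable but the dependence is
  structural.
- The background estimator excludes other lesions only through their
  bounding boxes, not their blurred tails; lesions closer than the
  shell width can still raise SUVbgd.
- Phantom and cohort generators are calibration instruments, not
  clinical simulators (see above); cohort-level quantities such as
  ROC AUC or 5-year survival splits depend on the simulated effect
  size and should not be compared to any particular clinical cohort.
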