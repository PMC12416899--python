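# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limits of the `crossdecode` pipeline.

## Task structure and GLMs

Three task designs are generated and modeled:

* **Face search.** Each trial: 1 s face cue → 8 s blank delay → 0.25 s
  search display → 8.75 s inter-trial interval (18 s per trial). Per run,
  exactly `trials_per_run` trials with each of the four faces cued
  `trials_per_run/4` times and an exact valid/invalid split
  (`trials_per_run × valid_fraction` must be an integer; default 16
  trials, 12 valid / 4 invalid, 8 runs). Invalid trials pair the target
  with a scene category other than its associated one. The GLM has 11
  task regressors per run: 4 × 1 s cue (one per face), 4 × 8 s delay
  (one per cued face), and 3 × 1 s display regressors (valid, invalid,
  error response). The display is modeled with a 1 s boxcar although it
  is on screen for 0.25 s; the brief events share a common modeled
  duration. A `search_delay_split` variant splits each delay regressor
  into two 4 s halves (15 regressors) for early/late-delay analyses.
* **Face/scene 1-back.** Per run: 4 trials for each of 4 faces and 4
  scene categories plus 6 repeat trials = 38 trials; 1 s sample + 8 s
  delay. The per-run reading of these counts keeps run-wise chunks
  balanced for decoding. Repeat trials are flagged and modeled by a
  single 1 s regressor (17 task regressors in total: 8 sample + 8 delay
  + repeat); they are never decoding samples. The task's inter-trial
  interval is not part of the trial description and is exposed as a
  parameter; the default (8.75 s) matches the search task so the two
  GLMs are structurally compatible. Scale-reduced test configurations
  use a shorter ITI to keep runs short.
* **Associative learning** (behavioral only): per face, 18 match and 9
  nonmatch trials (3 from each other category), 108 trials total.
* A 6-regressor, 4 s-block localizer scheme is provided for functional
  ROI definition.

The HRF is the SPM-convention double gamma (peak delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s support), peak
normalized to 1, oversampled 16× and sampled at scan onsets after
convolution. Estimation is voxelwise OLS without prewhitening, which
makes the forward model exactly invertible on noiseless data (the test
suite asserts recovery to < 1e-6 relative error); AR(1) prewhitening is
available behind a flag. Six motion columns are appended when a motion
table is supplied, plus a constant. Design columns that are all zero
(e.g. the error-display regressor in an error-free synthetic run) are
excluded from estimation and reported with coefficient 0, so the design
always carries its full named regressor set without becoming rank
deficient. No high-pass filtering is applied by default.

## Synthetic BOLD and ground truth

BOLD is generated by the forward model `y = X B_true + ε`: the same
design matrix the analysis fits, times true betas, plus Gaussian noise
(optionally AR(1)). Condition patterns are fixed random Gaussian vectors
per ROI (not orthogonalized); an ROI's "information assignment" says
which of the four schemes it supports, and cross-decodability is created
by *reusing patterns across tasks*:

* `cue_face`: face f's pattern appears in the search cue-f regressor and
  in the 1-back face-f sample regressor;
* `delay_scene`: the pattern of scene σ(f) appears in the search delay-f
  regressor and scene s's pattern in the 1-back scene-s delay regressor;
* `cue_scene` / `delay_face` analogously.

The default assignment emulates the paradigm's target finding: face
information at the cue in a face-selective ROI, associated-scene
information in the delay in scene-selective/frontal ROIs, plus an
uninformative control ROI. The association σ defaults to the identity
pairing — labels are arbitrary, so this loses no generality, and tests
also exercise non-identity bijections. Display regressors carry no
category pattern by default (decoding targets cue/delay periods); the
search ITI is unmodeled baseline, mirroring a GLM with no ITI regressor.

Defaults follow the study conditions: 26 subjects, 8 search runs × 16
trials at 75% validity, 4 one-back runs, TR 1.5 s, 3 mm isotropic
voxels. The grid (16 × 16 × 10) and box ROIs are desk-scale stand-ins
for a brain volume; amplitude 2 and noise sd 1 give strong but not
saturated single-subject decoding. What the generator does *not*
emulate: physiological and scanner noise structure, spatial
autocorrelation, HRF variability across subjects/regions, eye movements,
and realistic stimulus images. Passing tests therefore demonstrate the
*statistical machinery* (calibration, recovery, invariances) — not that
real scanner data would yield these accuracies.

Behavior: per-subject RTs are Normal with a subject-specific validity
effect drawn so the across-subject standardized paired difference
(Cohen's dz) targets the configured value (default 0.678); trial noise
(sd 0.15 s) and across-subject effect spread (sd 0.05 s) enter the
targeted sd so the recovered dz is unbiased (checked by simulation).
Accuracy is Bernoulli, higher on valid trials.

## Decoding

Normalization is per-voxel z-scoring with statistics from the training
set only, applied unchanged to the test set; zero-variance voxels map to
0. A per-sample centering alternative is available. The pairwise bank
holds one soft-margin linear C-SVC per unordered condition pair (C = 1),
trained on that pair's samples; mean accuracy is the unweighted mean of
the six pair accuracies (the design is balanced, so weighting is moot).
Scene-scheme test samples are relabeled to the face associated with
their scene category before scoring — the only coherent way a
face-trained classifier can score scene patterns under the learned
bijection.

The SVM solver is an in-package SMO dual solver (maximal-violating-pair
working-set selection, tolerance 1e-4), compiled with numba; a fit on
these problem sizes costs ~15 µs, which is what makes 10⁶-fit
permutation suites tractable. The test suite verifies prediction-level
and primal-objective agreement with libsvm on random problems. Decision
scores of exactly 0 classify to the smaller condition id — a
deterministic, documented tie-break.

## Inference

The permutation null shuffles *training* labels within runs (preserving
the chunk structure), re-runs the train→cross-test stage, and averages
across subjects per iteration, pairing subject streams by iteration
index; p = (#{null ≥ observed} + 1)/(N + 1), one-sided. Because the
z-scoring statistics are label-independent, normalization is computed
once per subject rather than per iteration — an algebraically identical
shortcut asserted by a test that compares the fast path against the
object API. Bonferroni families default to the number of ROIs per
scheme. All permutation streams derive from one master seed through
`numpy` SeedSequence spawning, so results are reproducible and
parallelizable.

Type-I calibration is verified empirically: over 200 fully simulated
no-information cohorts (8 subjects, 500 permutations each), the
uncorrected rejection rate at α = 0.05 falls inside the exact binomial
95% interval [0.024, 0.087].

The power computation uses the noncentral t distribution (noncentrality
dz√n, df n−1) and returns the smallest n ≥ 2 reaching the requested
power; `scipy`'s stable survival function is used because the CDF
underflows at large noncentrality. Note that at n = 2 (df = 1) the
t distribution's tails are so heavy that even dz = 10 yields only ~0.78
power two-tailed — the n = 2 floor engages only for far larger effects.

## Searchlight and TFCE

Spheres are defined in world millimetres through the affine (so
anisotropic grids work), truncated at the analysis mask; a 9 mm radius
on a 3 mm grid gives 123 voxels. Each sphere runs the identical decoding
chain as the ROI analysis; equality on matched voxel sets is asserted.
Maps are smoothed with a Gaussian kernel (sigma = FWHM/(2√(2 ln 2)) per
axis, mm→voxels), nan-aware with mass renormalization at mask edges.

TFCE integrates e^E · h^H · dh over thresholds (defaults E = 0.5, H = 2,
dh = max/100, 26-connectivity — the literature-standard values; the
integration is verified against a brute-force 1-D enumeration and the
single-peak closed form h³/3). Group correction: subject maps are
chance-centered (accuracy − 0.5, or contrast vs 0), the group t-map is
TFCE-enhanced, and a sign-flip permutation of subject maps records the
maximum TFCE statistic per iteration, giving FWE-corrected voxel
p-values; cluster tables report components below a configurable p
threshold (default 0.005) with at least a configurable size (default 50
voxels). Zero-variance voxels get t = 0 rather than ±∞.

## Problem sizes in tests and the acceptance script

The statistical suites run at deliberately reduced scale — grids of
6×6×4 to 10×10×6 voxels, 2–4 search runs of 8 trials, 1–2 one-back runs
with a shortened ITI, cohorts of 5–8 subjects, 199–1,000 permutations —
sizes chosen so the whole suite completes in about 1.5 minutes while
every calibration check retains enough replicates (200 cohorts for the
type-I rate, 20 seeds for the recovery rate) to be statistically
meaningful. "At chance" in the recovery suite is defined as a group mean
accuracy within 0.1 of 0.5, which at these cohort sizes is a far more
stable criterion than a per-seed hypothesis test whose null p is
uniform.

## Known limitations

* OLS without prewhitening is exact for the white-noise generator but
  mildly anti-conservative under strong AR(1) noise; the AR(1) flag
  exists but is not the default.
* The permutation engine shuffles training labels; shuffling test labels
  is a valid alternative the package does not currently implement.
* Searchlight centers iterate in Python (numba accelerates only the SVM
  inner loop); whole-brain maps at full resolution are feasible but not
  fast.
* Functional ROI definition supports uncorrected-p and raw-statistic
  thresholds; no FWE method for the localizer is built in, so
  FWE-style thresholds must be supplied as raw statistic cutoffs.
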