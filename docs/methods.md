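# Methods

This note documents the models, the synthetic-data generator, the
statistical procedures and the numerical choices, in the package's own
terms.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Acquisition model and serum kinetics

The default acquisition layout is one baseline run of 450 volumes and
three post-injection runs of 900 volumes at TR = 1.18 s, starting at −30,
0, 30 and 80 minutes relative to the endotoxin injection (`RunSpec`).
Blood is sampled every 30 s during the post-injection runs, every 10 min in
the gaps, and sparsely out to 240 min; the baseline blood sample is the
last sample before the first post-injection run.

Serum pulses are gamma-density curves
`a · x^k · exp(k(1−x))`, `x = (t − onset)/(peak − onset)`, which are zero up
to onset, unimodal with the maximum exactly at `peak`, and smooth.  The
shape parameter k is needed beyond (onset, peak, amplitude) to control the
decay: with the ACTH timing (onset 50 min, peak 130 min) a shape of 2
leaves ~36 % of the peak at 240 min, violating the return-to-baseline
behaviour the pulse must emulate (≤ 10 % of peak at 240 min).  Defaults,
chosen once from the kinetic description and not revisited: TNF onset 25,
peak 65, amplitude 250 pg/mL, shape 3; ACTH onset 50, peak 130, amplitude
55 pg/mL, shape 6.  Cohort curves add per-subject amplitude jitter
(CV 0.15) and small sampling noise.

## Phantom and embedded sources

`make_phantom_anatomy` builds an ellipsoidal brain with a GM shell, WM
core, ventricle + rim CSF, and a compact ellipsoidal ROI
(radii 5.0 × 4.4 × 3.9 voxels, ≈ 360 voxels at the default 24³ grid —
comparable to an anatomical hypothalamus mask at study resolution) near
the volume centre.  The tissue inside the ROI neighbourhood is overridden
to deep grey matter with a deliberate WM pocket on the +x side, so
WM-embedded negative-control sources can live *inside* the ROI — the
configuration the specificity filter must catch.

The canonical ground truth embeds five compact Gaussian blobs
(σ = 1 voxel, truncated at r = 2.2):

| source | coupling | run amplitudes | tissue |
|--------|----------|----------------|--------|
| 1 | TNF (negative) | 1, 1, 3, 3 | GM, cortical satellite |
| 2 | ACTH (negative) | 1, 1, 1, 3 | GM, cortical satellite |
| 3 | none | flat | GM |
| 4 | none | flat | WM pocket |
| 5 | TNF (positive) | flat | GM |

Group-level time courses: coupled sources are the z-scored serum curve
resampled at the volume times plus white fast noise (zero-mean, unit sd
per run, × the run-amplitude multiplier), with the noise scale solved by
root finding so the block-downsampled course correlates with the
downsampled serum curve at exactly the target |r| (default 0.92).
Uncoupled sources get the same fast fluctuation plus slow drift
(correlation time of half a downsampling block, demeaned per run), giving
their block means realistic slow variability of their own; without it,
the block means of an uncoupled component's *estimated* time course are
dominated by regression cross-talk from the strong serum-coupled sources
and produce spurious coupling.  Two exactness choices matter downstream:

- The fast vectors of all sources are mutually orthogonalised per run,
  and each drift vector is orthogonalised against the whole fast set.
  Independent draws would leave per-run *sample* correlations of ±0.2
  between source time courses (few effective degrees of freedom per run);
  shared by every subject, such fluctuations modulate each component's
  unique regressor variance from run to run and masquerade as
  connectivity changes in the paired run comparison.
- The drift is demeaned per run, so an uncoupled source cannot mimic the
  step-like between-run serum profile by chance, and orthogonalisation
  keeps every source's per-run fluctuation sd exactly on its amplitude
  profile — "run-modulated" is a property only the modulated sources have.

Subject data are
`baseline + amplitude · Σ map_k ⊗ tc_k + drift + white noise` with
baseline 1000 (so grand-mean scaling is exercised nontrivially), additive
per-subject smooth time-course jitter (10 % of each course's sd), a
spatially smooth slow drift field, and white noise at `noise_sd` equal to
the signal amplitude — per-voxel SNR 1 at blob peaks, the hardest
condition the verification targets state.  Subject variability is
deliberately *additive only*: a multiplicative per-subject amplitude factor
is a rank-one effect across voxels, and under n = 6 sign flipping such
effects admit variance-collapsing sign patterns whose TFCE maxima destroy
the power of the permutation test — a pathology of scalar subject effects
that spatially incoherent variability (estimation noise) does not have.

What the generator does **not** emulate: hemodynamic-response convolution,
motion, physiological noise spectra, susceptibility distortion,
subject-specific anatomy (spatial maps are shared across subjects — the
regime a single group ICA on concatenated data can recover).  Passing
tests therefore show the *pipeline arithmetic* is right under known ground
truth, not that the method is robust to real-data artefacts.

## Preprocessing

Grand-mean scaling multiplies each run by `target / global 4D mean over
in-brain voxels` (target 10000).  The high-pass filter projects out the
discrete-cosine components with frequency below the cutoff
(K = ⌊2·T·TR·f_c⌋ basis vectors) and keeps the temporal mean; it is
idempotent, and attenuation is testable in closed form by projecting
sinusoids on the same basis.  Smoothing is a per-volume 3D Gaussian with
σ = FWHM/(2√(2 ln 2)) per axis in mm (reflect boundary), applied to the
whole-brain stream only — small-ROI analyses use unsmoothed data.

Two matrix forms feed the analysis: the ICA input (per subject-run block:
voxelwise demeaned, variance-normalised by default) and the dual-regression
input (masked but *not* demeaned — between-run signal levels are exactly
what the serum-coupling criterion measures; stage 1 is insensitive to
spatially uniform offsets because the map regressors are demeaned over
voxels).

## Masked ICA

Spatial ICA of the concatenated matrix X (T_total × V): SVD reduction to d
dimensions (whitened voxel representation, covariance identity within
1e-8), then symmetric fixed-point iteration with the log-cosh contrast
(tol 1e-5, max 500 iterations, 3 restarts with seed offsets, best restart
by the negentropy proxy).  Sign ambiguity: maps oriented to positive skew.
Order: explained variance (mixing column norm).  Map z-scaling divides by
the background σ of a two-class mixture fit — Gaussian background plus
shifted-Gamma positive tail, fitted by EM; voxels with posterior signal
probability > 0.5 form the thresholded map; a degenerate fit (signal
weight < 1 %, or non-convergence) falls back to |z| > 3 with a flag.
`scan_dimensionalities` emits per-d summaries and winner-take-all label
volumes; choosing the anatomically correct d is a human judgement the
package supports but does not automate.

## Dual regression and specificity

Stage 1: `timecourses = X · pinv(S)` with maps demeaned over voxels
(conditioning guard at 1e8; a `demean_maps=False` option exists because
over a small mask the subtracted map mean couples every component's time
course to every other component's signal).  Stage 2: voxelwise OLS on the
demeaned (optionally unit-variance) time courses; z = β/SE at T − d − 1
df.  The z maps are invariant to per-regressor scaling, so the
variance-normalise flag affects β only.  When stage 2 targets the same
voxels stage 1 was computed from, each voxel's stage-1 contribution is
removed from its own regressors by an exact rank-one downdate
(`exclude_target_voxel`, on by default): with only a few hundred mask
voxels, the voxel's own noise otherwise enters its regressor with a
deterministic weight shared by every subject, and the resulting bias —
negligible for whole-brain masks — passes through the run-specific
regressor correlation structure and does not cancel in run comparisons.  Specificity: Q as defined in the README over
whole-brain |z| of the group-mean maps (absolute values so anticorrelated
but tissue-specific components are not penalised); exclusion below
mean − 1 sample SD across components; an infinite quotient (zero WM/CSF
mass) is flagged and treated as maximally specific.

## Permutation inference

TFCE: `Σ_h e(h,v)^E · h^H · dh` from h = dh to the statistic height, with
E = 0.5, H = 2, 26-connectivity and dh = max/100 by default (the standard
parameterisation); negative values are enhanced on the negated map and
negated back.  One-sample and paired tests build the null by sign flipping
(exhaustive when 2^n ≤ n_perm — 64 patterns at n = 6 — else seeded random
with the identity always included).  Zero-variance voxels: 0/0 → statistic
0; sd 0 with nonzero mean → capped at ±1e6.

Tail conventions: the generic tests default to one-sided 'greater' (signed
TFCE maximum; attainable minimum p = 1/n_perm, matching standard
permutation tools).  The run-pair comparison uses an exact two-sided test
(maximum |TFCE|); because sign patterns come in (s, −s) pairs its
attainable p values are multiples of 2/n_perm.

Robust statistic: the voxelwise t is clipped at |t| = 20 before
enhancement, identically for the observed and every permuted map (the
permutation test remains exact).  With a handful of subjects, sign
patterns that happen to align a few similar |differences| at one voxel
collapse the variance denominator and produce t of 30–50; since a
singleton's TFCE grows as t³, such voxels would otherwise dominate the
maximum-statistic null and destroy the power of the paired test.

The run-pair comparison (criterion 2) tests every unordered pair of
post-injection runs and applies **one** max-statistic FWE correction across
voxels *and* run pairs per component, using the same sign pattern across
the pair family per permutation.  Correcting each pair separately and
taking the union rejects a true null with probability
1 − (1 − 2/64)^pairs ≈ 9 % — an error rate that would dominate the
end-to-end selection; the family correction controls it at alpha exactly.
With n = 6 the attainable minimum p is 1/64 ≈ 0.016, so a whole-brain
threshold of p < 0.01 cannot be reached under exhaustive sign flipping;
the one-sample stage reports unthresholded statistic/TFCE/p maps and an
(empty at n = 6) thresholded map, and the network analysis uses the
unthresholded maps, as intended.

## Coupling and selection

BOLD downsampling: mean of the final baseline block, then consecutive
non-overlapping block means per post-injection run (10 points for the
default design).  Serum downsampling: the baseline sample, then means of
consecutive blocks of raw 30-s samples from each run's start (12 samples ≈
354 s of BOLD; the ~6 s per-block misalignment is accepted).  Criterion 1
correlates the group-mean stage-1 time courses (subject average) with each
marker; two-tailed p from the t transform at n − 2 df; Bonferroni over
retained components × 2 markers.  Selection is the conjunction of the two
criteria on the same retained set, with the full decision trace (marker,
run pair, p) logged and exported.  The serum change test is a classical
two-tailed paired t (baseline vs 120 min), reported as mean ± SD.

## Networks

Pairwise Pearson correlation of the unthresholded whole-brain maps over the
brain mask; complete-linkage clustering of the *rows* of the correlation
matrix under Euclidean distance (the heat-map tooling convention — items
clustering together when they relate to all maps similarly); deterministic
tie-break by input order; exports as labelled CSV, Newick and SVG.

## Problem sizes used in the verification runs

The replicate-based checks (end-to-end selection, ICA recovery, FWE
calibration) run at a desk-scale layout chosen as the package's standard
verification condition: grid 24³ (3 mm voxels), 6 subjects, runs
[150, 300, 300, 300] at TR 1.18 s, 100-volume BOLD blocks and 4-sample
serum blocks — the identical 10-point downsampling grid and
3-blocks-per-run structure as the full design at a fraction of the data
volume.  Single-shot oracle checks (downsampling arithmetic,
pseudoinverse identities, TFCE brute force, enumeration) use the
full-design run lengths or small closed-form grids, where runtime is
negligible.

## Known limitations

- n = 6 permutation inference has only 64 sign patterns; p-value
  granularity (1/64, or 2/64 two-sided) is intrinsic, and the 0.01
  whole-brain threshold is unattainable at this sample size.
- The mixture-model threshold assumes a unimodal positive signal tail;
  strongly bimodal maps fall back to |z| > 3.
- The specificity rule is relative (mean − 1 SD across components): with
  very few components a single outlier shifts the cutoff.
- The generator's shared spatial maps make group ICA exactly identifiable;
  real between-subject anatomical variability would degrade recovery in
  ways these tests do not measure.
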