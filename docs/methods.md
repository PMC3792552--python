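# Methods

This note documents the statistical model, the pipeline conventions, the
synthetic-data generator, and the numerical choices in `localfc`, in the
order the pipeline runs.

## Frame accounting and motion scrubbing

Runs are acquired with a fixed number of volumes (default 185 at
TR = 2 s); the first 5 are discarded mechanically to avoid T1
equilibration transients, leaving 180 analysis frames. Motion traces
(3 translations in mm, 3 rotations in degrees) are inputs, not
estimated.

Framewise displacement for the step between frames *t−1* and *t* is the
Euclidean norm of the 6-vector of parameter differences, with rotation
differences converted to millimetres of arc on a sphere of radius 50 mm
(the common head-radius convention; configurable). Censoring applies
three rules: a suprathreshold step (default > 1.0 mm) censors the frame
before the movement, the movement frame, and the following frame; runs of
at most 10 retained frames between two censored frames are censored too;
and subjects retaining fewer than 80% of frames are excluded (exactly 80%
is kept — the exclusion is strict). A conservative variant at > 0.25 mm
defines a low-motion subsample. RMSD (the root mean square of per-step
displacement) is computed over all steps, before censoring; computing it
on retained steps only is possible by calling `rmsd` on the retained
subvector. Which endpoint of a suprathreshold step counts as "the" moved
time point is a convention; the choice here (the later endpoint, with its
two temporal neighbors) is fixed and covered by tests.

## Temporal preprocessing

Band-pass: zero-phase (forward–backward) second-order Butterworth,
0.008–0.08 Hz by default. Zero-phase application is a deliberate choice —
causal filtering would phase-shift neighboring time series relative to
nuisance regressors. The series mean is removed before filtering so
constants map exactly to zero.

Nuisance model: 16 labeled regressors — six motion parameters, their
derivatives, mean white-matter and ventricle signals (from masks eroded
by one pass of 6-connectivity erosion, to limit partial-volume
contamination), and the two tissue derivatives. Derivatives are backward
differences with a leading zero. With global-signal regression enabled,
the gray-mask mean and its derivative are appended (18). Every nuisance
column is filtered with the same band-pass applied to the data. An
intercept and a linear scanner-drift term are always included in the
regression but are not counted among the 16. Identically-zero columns
(e.g. derivatives of a constant trace) are dropped before fitting; any
remaining rank deficiency is an error that names the collinear columns.

Regression is ordinary least squares per voxel, fitted on retained
(non-censored) frames only; residuals for censored frames are evaluated
from the fitted coefficients so that frame indexing is preserved, and
censored frames are excluded again from every downstream statistic.

Order convention: the pipeline filters, then regresses (with filtered
regressors), then computes statistics on retained frames. Filtering and
regression are both linear but do not commute here: with a 0.008 Hz
lower edge the filter's transients span a 6-minute run, and the measured
sensitivity to order is roughly 20% RMS of the residual even for
band-limited data. The chosen order is therefore a documented convention,
not an equivalence; a test bounds the order sensitivity.

## Spatial smoothness

Smoothness is estimated per axis with the classical gradient-variance
estimator: `FWHM = d·sqrt(−2 ln 2 / ln(1 − s²_diff/(2 s²)))`, where
`s²_diff` is the variance of in-mask first differences and `s²` the
in-mask voxel variance; axes rougher than white noise report a 0 mm
sentinel, and 4D inputs average over frames.

"Blur to FWHM" raises a dataset to a target smoothness (default 6 mm,
tolerance 5%) by repeatedly applying small in-mask Gaussian increments
(normalized masked convolution — no bleed across the mask edge) until the
estimate enters the tolerance band. Discrete truncated kernels deliver
smoothing that only loosely tracks the nominal quadrature increment —
`scipy`'s kernel radius jumps at half-integer sigmas, and thin masks can
over-deliver — so each increment is applied provisionally and accepted
only if it does not overshoot the band; rejected steps back off the
kernel width. Accepted iterates are monotone non-decreasing in
smoothness. Smoothing placement is configurable: the primary pipeline
computes ReHo on unsmoothed data and equalizes the *statistic maps* to
6 mm before group comparison; a variant smooths the BOLD data before the
statistic; density analysis conventionally uses pre-smoothed data.

## Local connectivity statistics

ReHo: each voxel's time series is rank-transformed once (midranks for
ties) and reused by all neighborhoods containing it; the printed W
formula is evaluated from neighborhood rank sums, so the whole-map cost
is one ranking pass plus one accumulation per neighborhood offset.
Neighborhoods are clipped at the analysis-mask boundary rather than
dropping boundary voxels; the effective K is recorded per voxel for
auditability. Zero-variance member series are excluded with K
decremented; centers left with K < 2 are undefined. No tie-correction
term is applied to W (ties have measure zero for continuous BOLD; with
heavily discretized data W's ceiling drops slightly below 1 — known
limitation).

Metric neighborhoods use strict center-to-center distance, which makes
the 6 mm sphere at 3 mm isotropic exactly the 27-voxel cube and gives 437
voxels at 14 mm. (An often-quoted 407-voxel count for 14 mm is not
reproducible under any center-distance convention; this package documents
its own enumeration and does not force the other number.)

Degree: neighbors within the strict radius, center excluded, counted when
Pearson correlation over retained frames strictly exceeds the threshold
(default 0.25).

Standardization divides by the population SD (ddof = 0) over the analysis
mask after subtracting the mask mean; the analysis and standardization
masks coincide by default (configurable). Undefined voxels are excluded
from the moments and stay undefined.

## Group inference

Voxelwise comparison: pooled-variance two-sample t with df = n₁+n₂−2,
two-sided p; positive t means group 2 > group 1. Voxels with zero pooled
variance or any undefined subject value are missing.

Cluster-extent correction re-implements the Monte-Carlo recipe: iid
Gaussian noise on the mask grid, one Gaussian smoothing pass to a target
FWHM, in-mask standardization, two-sided voxelwise threshold, largest
suprathreshold component (positive or negative, face connectivity by
default) recorded per iteration; the minimum cluster size is the smallest
k whose null exceedance fraction is ≤ α. A single Gaussian pass rather
than an iterative blur-to-FWHM is used for speed; the difference is
absorbed by the smoothness calibration below.

Smoothness calibration: statistic maps built from overlapping rank
neighborhoods have spatial autocorrelation with heavier-than-Gaussian
tails, and the gradient-variance estimator (which reads only sub-voxel
curvature) understates the correlation that drives cluster extents —
measured lag-2 autocorrelation of null ReHo maps was 0.24 where a
curvature-matched Gaussian predicts 0.05, and the resulting extent
threshold was anticonservative (15% family-wise error at nominal 5%).
The pipeline therefore feeds the extent simulation an *ACF-matched
equivalent FWHM* (`equivalent_gaussian_fwhm`): the empirical in-mask
autocorrelation at axis lags 1–3 is measured and each usable lag is
converted to the FWHM of the Gaussian ACF passing through it. With this
calibration the permutation-measured family-wise error on a null
synthetic cohort is 3% at nominal 5%. This mirrors the field's move from
curvature-based FWHM to ACF-based cluster simulation.

Cluster tables report sign (over/under-connectivity), voxel count,
volume in μl (count × voxel volume), and the max-|t| peak in world mm.
Connectivity is face-adjacency by default (configurable to face+edge or
face+edge+corner). Combined-cluster series average each subject's map
over the union of same-sign clusters; their Pearson correlations with
behavioral scores are reported raw and flagged exploratory — no
multiple-comparison correction is applied or implied.

## Synthetic cohorts

The generator emulates the target acquisition: 185 volumes at TR 2 s,
3 mm isotropic grid (default 24³ — desk-scale while supporting 14 mm
neighborhoods), concentric-shell head model (ventricle core, white shell,
gray rind; gray ⊂ brain, tissues pairwise disjoint), two groups (default
29 + 29, configurable).

Background activity: white noise band-limited to 0.01–0.08 Hz per voxel,
then spatially smoothed to the design FWHM (default 6 mm) and rescaled to
unit temporal variance; fluctuation amplitude 5 on a baseline of 1000
(≈ 0.5% signal change, a typical resting-state fluctuation scale). All
planted signals are band-limited below 0.1 Hz by construction so the
band-pass stage does not destroy them.

Planted local coherence: each effect region (a sphere intersected with
gray matter, default ~100 voxels ≈ 2700 μl — the volume scale at which
cluster-level effects are typically reported) carries one shared
band-limited signal; member voxels mix it with their own background as
`√c·shared + √(1−c)·background`, so the expected correlation between two
member voxels with independent noise equals the coherence level *c*
exactly, and variance is preserved (coherence is induced without changing
smoothness — the two confounds stay separable). An "increase" region
applies coherence to the case group, a "decrease" region to the control
group. Default level 0.5 with subject-level SD 0.1 (clipped to [0, 1]):
a mid-scale effect; no published effect-size scale exists for these group
differences, so the level is a free parameter chosen once, not calibrated
to any reported t-values.

Nuisance structure: linear drift (amplitude 3 intensity units per run),
shared white-matter and ventricle signals (amplitude 2) and a global
brain-wide fluctuation (amplitude 1), all band-limited. Motion: a
random-walk jitter of 0.02 mm/deg per step plus Poisson(2) transient
spikes of 0.2–1.5 mm per subject (so a realistic minority of frames is
censored and occasional subjects approach the exclusion boundary);
explicit per-subject spike lists override the random spikes.

Behavioral scores are continuous pseudo-severity values (mean 10, SD 3)
drawn with a configurable correlation (default 0.5) to each subject's
mean planted coherence; only the correlation mechanics are modeled, not
score discreteness.

Randomness: every subject draws from a substream seeded by
`SeedSequence([design_seed, subject_index])`, so cohorts are bitwise
reproducible and growing a cohort does not reshuffle existing subjects.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: scanner physics (slice timing, field
inhomogeneity, T1 decay), anatomically realistic geometry or ACF shapes,
non-stationary motion artifacts coupled into the BOLD signal, or
physiological noise spectra. Tests on these cohorts validate the
*statistical machinery* (correct formulas, calibrated error rates,
recoverable planted effects), not robustness to real-scanner artifacts.

## Problem sizes used by the test suite

The suite exercises the pipeline at desk scale chosen for a single CPU:
null calibration on a 16³ grid with 8 + 8 subjects and 200 relabelings;
planted-effect recovery on 20 replicate 24³ cohorts of 8 + 8; oracle
equivalence for W on 10,000 random clusters; smoothness control on 32³
fixtures. The statistics are seeded and deterministic.

## Known limitations

- The KS uniformity check treats spatially correlated voxels as
  independent samples, which makes it anticonservative; it is retained
  as specified, under a fixed seed.
- The ACF-equivalent FWHM collapses a non-Gaussian ACF to a single
  Gaussian width; it matched the permutation null well on these cohorts
  but is still an approximation (a full ACF-shaped noise model is the
  natural extension).
- `blur_to_fwhm` requires the mask to support the target smoothness;
  very thin shells (≲ 2 voxels) at small grids may fail to converge —
  the pipeline surfaces this as an error rather than silently
  under-smoothing.
- Scrubbing order (filter → regress → censor-aware statistics) is a
  convention; censored frames influence filtering transients.
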