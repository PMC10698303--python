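# Methods

## The task and its factorial structure

The auditory local-global paradigm presents five-tone patterns that are
either locally standard (`xxxxx`, five identical tones) or locally
deviant (`xxxxY`, the fifth tone differs). Within a block, one pattern
type is the *global standard*: it is the only pattern during a
25-pattern habituation phase and then 80% of the 110 test patterns; the
other type is the *global deviant* (rare, 20%). Blocks of both standard
types appear in every session in counterbalanced order with
counterbalanced tone sets (A: 350/700/1400 Hz; B: 500/1000/2000 Hz).
Patterns last 650 ms and are separated by 1.5 s, so onsets advance by a
2.15 s stimulus onset asynchrony. Crossing local deviance with global
rarity yields four pattern-type cells and dissociates
stimulus-probability deviance (a rare `xxxxY` among `xxxxx`) from
sequence-structure deviance (a rare `xxxxx` among `xxxxY`).

`paradigm.generate_block` places the rare patterns uniformly at random
over test positions subject to a minimum gap (default: no two adjacent
rares); the uniform law over feasible placements is obtained by the
standard combinatorial bijection, so placement is exactly uniform, not
greedy. Habituation rows are labelled distinctly; downstream analyses
count them as frequent by default (they carry the standard pattern) and
can exclude them by flag. Individual tone onsets inside the 650 ms
pattern are not modelled — at fMRI and pupil timescales only the
pattern onset matters.

## ROI signal model and preprocessing

ROI series are scan-by-scan means over binary masks (probabilistic maps
binarised at p >= 0.05, inclusive; averaging is unweighted). Before any
epoch analysis each session is processed in this order:

1. high-pass via discrete-cosine nuisance regression, cutoff period
   128 s, with K = floor(2·N·TR/128) basis functions (the SPM drift
   convention, implemented as regression rather than a causal filter so
   the operation is idempotent and phase-free);
2. least-squares removal of confounds with an intercept — six motion
   parameters, the 4th-ventricle signal, and the 18 physiological
   regressors when available (any subset may be supplied);
3. z-scoring of the residual (population SD).

TSNR is mean(raw)/SD(residual after polynomial detrending of order 3).
Rank-deficient confound matrices fall back to the pseudo-inverse with a
warning; a residual with (near-)zero variance raises a degenerate-signal
error rather than propagating NaNs.

Mask shifting for the anatomical-specificity analysis is a pure integer
translation along one grid axis; voxel count is preserved, and moving
any voxel off the grid is an error. Provenance records the offset in
voxels and millimetres (offset x voxel size).

## Physiological nuisance basis

Cardiac phase is 0 at each detected pulse peak and linear in time to
2·pi at the next peak (peak detection: local maxima with a refractory
distance of 0.5/expected rate). Respiratory phase applies amplitude
histogram equalisation signed by the trace slope, so inhalation maps to
(0, pi) and exhalation to (pi, 2·pi) with phase 0 at end-expiration;
for a sinusoidal trace this is exactly linear-in-time phase. The
regressor matrix evaluates sin/cos of k·phase for k = 1..order per
modality plus, per interaction order, sin/cos of the sum and the
difference of the two phases (4 columns per order). Orders (4, 3, 1)
therefore give 2·4 + 2·3 + 4·1 = 18 columns, evaluated at one reference
instant per volume (default TR/2, the slice-timing reference). The
sum/difference interaction basis is adopted because it reproduces that
published column total; the upstream tool's exact construction is not
documented.

## Epoch statistics and cluster-level inference

The preprocessed series is linearly upsampled (grid spacing
TR/factor; the reference analyses used factor 1000) and epoched from
−2 to 12 s around each onset; the mean over −2..0 s is subtracted per
epoch. Events whose window crosses a session edge are dropped. Cell
means and the factorial contrasts (global = rare − frequent, local,
and the difference-of-differences interaction) are formed per subject
from cell means, which balances the unequal trial counts.

Group inference over peristimulus time uses the paired t statistic
t(τ) = mean(Δ(τ)) / (SD(Δ(τ))/√n) and Cohen's d(τ) = t(τ)/√n (the
paired convention; the published t/d/n triplets satisfy it). Clusters
are maximal runs with |t| above the two-sided t threshold at the
cluster-forming alpha (0.05, df = n−1); the cluster statistic is the
mass (sum of t in the run). The null is the maximum absolute cluster
mass over random per-subject sign flips, and
p_FWE = (1 + #{null ≥ observed}) / (1 + n_permutations). Because sign
flips leave each subject's squared data unchanged, permuted t curves
need only permuted means, which makes 10^3–10^4 permutations cheap.
The implementation is cross-checked in the test suite against MNE's
one-sample cluster permutation test (identical t curves and cluster
extents; p values within Monte-Carlo tolerance).

Peak-latency differences between conditions take the argmax of each
group-mean curve inside a search window (ties resolve to the earliest
timepoint, logged) and a subject-level percentile bootstrap (default
10,000 resamples) for the 95% CI; the method is a reconstruction, since
the reference analysis does not specify one.

## FIR and GLM models

The canonical HRF is the SPM-convention double gamma (peak delay 6 s,
undershoot delay 16 s, dispersions 1 s, ratio 1/6, 32 s support),
scaled to unit peak. FIR designs bin post-stimulus time over 0–12 s at
TR/5 resolution (48 bins) and by default model rare patterns only; a
flag models all four cells, which is needed for unbiased estimates when
frequent-evoked variance must not fold into the baseline. HRF designs
carry one convolved regressor per cell. Both append confounds, DCT
drift columns, and a per-session intercept. Subject-level estimation is
two-pass: OLS, AR(1) coefficient from lag-1 residual autocorrelation
pooled over sessions (clipped to ±0.99), Cochrane–Orcutt prewhitening
(first scan scaled by √(1−ρ²)), then GLS betas with contrast standard
errors from the whitened normal equations. Prewhitening is exact on
noiseless data. Scalar group tests are one-sample t; FIR beta
time courses route to the cluster permutation test.

## Pupillometry

Preprocessing: widen each annotated blink by 50 ms on both sides, merge
overlaps, interpolate linearly across each interval, zero-phase
(forward–backward) third-order Butterworth low-pass at 5 Hz, z-score
per session. Zero-phase filtering is chosen to avoid latency bias; the
reference pipeline names only the cutoff. Epochs span −0.5..3 s with a
−0.5..0 s baseline (the reference does not state the baseline window).
Exclusion boundaries follow the published wording exactly: an epoch is
dropped iff blinks cover strictly more than 20% of it; a subject is
excluded iff strictly fewer than 20% of epochs survive. Trial-wise
pupil–ROI coupling (a reconstruction; the reference never specifies
it) takes window-mean amplitudes per trial (pupil 0.5–2.5 s, ROI
2–8 s), correlates them within subject, and tests Fisher-z values
against zero at the group level; |z| is capped at 5 to guard r = ±1.

## Connectivity

Intrinsic signals are residuals after removing, per session, the four
HRF-convolved stimulus regressors plus confounds, then z-scoring.
Subject-level Pearson matrices are compared to zero per pair with a
one-sample t on Fisher-z values across subjects (the reference reports
Bonferroni-corrected Pearson correlations without naming the group
model); Bonferroni uses the n(n−1)/2 distinct pairs. Clustering is
agglomerative with average linkage on either 1 − r between subcortical
residuals or the cosine distance between rows of the
subcortico-cortical correlation profile matrix; trees export to newick.
Block-type condition splits assign scans to the span of each block.

## The synthetic generator: what it emulates and what it does not

Ground truth is a `GroundTruth` record. Key parameters (units, default,
why):

- `base_amplitude` (signal units, 0.5): auditory-evoked response common
  to all patterns.
- `global_effect` (signal units, 0.6): rare − frequent amplitude, i.e.
  0.6 in units of the unit-SD AR(1) innovations — the stated study
  condition for recovery experiments.
- `subject_sd` (signal units, 0.30): between-subject SD of the global
  effect. A ~50% coefficient of variation in true subject amplitudes is
  the realistic regime for subcortical event-related fMRI; much smaller
  values would make subject-level estimates pure estimation noise.
- `ar_coef` (0.4) and `innovation_sd` (1.0): AR(1) scan noise.
- `drift_amplitude` (0.5) with three 1/f-weighted slow cosines per
  session: scanner drift below the 1/128 Hz cutoff.
- `physio_gain` (0.15): the contamination is a random linear mix of the
  same RETROICOR basis the analysis constructs — the favourable case in
  which nuisance regression can in principle remove it exactly.
- `motion_gain` (0.1) on six random-walk motion parameters.
- `response_shape`: canonical by default; a boxcar-convolved "plateau"
  variant is available because the true subcortical response shape is
  unknown and the reference describes but does not parameterise it.
- Pupil: dilation kernel is a unit-peak gamma (mode ≈ 0.9 s, 3 s
  support) scaled per condition (rare 0.7, frequent 0.2 z — a 0.5 z
  rare−frequent difference); blinks are a Poisson process (0.2/s) with
  lognormal durations (median 0.2 s), a choice of convenience since
  blink statistics are not described in the reference.

Volume embedding gives voxels inside a mask the ROI signal at full
amplitude and lets it leak outward as a Gaussian of millimetre distance
(width 2 mm), so mask-shift analyses see a spatially attenuating
effect; voxel noise is white.

Not emulated: MRI artifacts (distortion, spikes, true motion
displacement), spatial autocorrelation of voxel noise, nonstationary
pupil gain, gaze-position artifacts, and any behavioural/counting
process. Passing tests therefore demonstrate estimator correctness and
calibration under the assumed signal/noise structure, not robustness to
every property of real recordings.

## Problem sizes and numerical choices in the test suite

Simulation-based tests run at reduced scale chosen once: one session
per subject (two counterbalanced blocks, ~480 scans at TR 1.25 s), 24
subjects, 50 replicates for recovery, 500 white-noise datasets with
1000 permutations for calibration, and epoch upsampling factor 4–8
(the factor only sets grid resolution; statistics are insensitive to it
well below 1000). The cross-method concordance check runs at the full
four-session design because subject-level concordance is a
data-quantity question. Type-I error of the cluster test calibrates to
0.05 within Monte-Carlo tolerance on white-noise nulls; power at the
default effect exceeds 70% for the global-effect cluster at n = 24.

Other numerical conventions: inclusive mask threshold (>= 0.05);
0-based voxel indices; earliest-maximum tie-break for peaks;
`AR` coefficient clipped to (−0.99, 0.99); Fisher z capped at |z| = 7
in connectivity and 5 in coupling; degenerate inputs raise typed errors
(`EmptyMaskError`, `DegenerateSignalError`, `UnusableTraceError`,
`PlacementInfeasibleError`) rather than returning NaNs.

## Known limitations

- The FIR default (rare-only, as in the reference) absorbs
  frequent-evoked variance into baseline/intercept terms; with dense
  frequent stimulation this is nearly constant and harmless, but sparse
  designs should model all cells.
- The cluster test treats time only; no voxel-wise or spatiotemporal
  clustering.
- Connectivity significance is across subjects; pooled-scan inference
  is not offered.
- The generator's favourable physiological contamination (same basis as
  the regressors) upper-bounds how well real RETROICOR cleanup works; a
  mismatched-phase variant can be emulated by supplying different
  traces to the contamination and the regressors.
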