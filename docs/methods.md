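# Methods

## Problem setting

The package implements a movement-attempt detector ("brain switch") for
EEG recorded under neuromuscular blockade. The physiological target is
the sensorimotor rhythm response: during executed, attempted or imagined
movement, mu-band (8–12 Hz) and beta-band (18–25 Hz) power over the
contralateral motor cortex drops (event-related desynchronization, ERD)
and transiently rebounds shortly after the movement ends (event-related
synchronization, ERS). The analysis is trial-based: an auditory cue marks
a 3-second task period, a classifier decides movement vs. no movement per
trial, and a sequential detector converts trial decisions into an alarm.

## Session model

Trial timing is deterministic: within a sequence, nine cues of 3 s are
spaced cue + silence = 7 s apart. Phase 1 holds four conditions (actual,
isometric, imagined, none) with 81 trials each over three blocks; phase 2
holds attempted vs. none with 54 trials each in one block. The totals
force 3 sequences per condition per block in phase 1 and 6 in phase 2;
the interleaving of sequences within a block is a seeded permutation
(the original protocol randomized it without reporting the order). The
self-paced rest between sequences is modeled as a fixed 10 s gap, and a
10 s lead-in precedes the first cue so the −1 s epoch baseline always
fits. The practice block of the original protocol contributed no
analyzed trials and is not generated.

## Synthetic data: what it emulates and what it does not

Each subject-session is simulated as:

* **Background**: independent Gaussian noise per channel, spectrally
  shaped to 1/f power above a 1 Hz corner (the standard broadband EEG
  assumption; the original study does not characterize its background),
  RMS `noise_scale` = 10 µV.
* **Rhythms**: two narrowband Gaussian sources (4 Hz bandwidth around
  10 Hz and 20 Hz), each RMS `rhythm_amp` = 10 µV at the focal channel,
  so the default rhythm SNR at C3 is 1. Both are projected with a smooth
  spatial gain (Gaussian in geodesic distance, width 0.5 rad) peaking at
  C3 and mirrored at C4 with gain 0.25 — a right-hand task drives the
  left hemisphere far more strongly.
* **ERD/ERS**: during each cue the rhythm amplitude is multiplied by
  (1 − `erd_depth`) for 0–3 s and by (1 + `ers_gain`) for 3.5–6 s after
  onset, with 200 ms raised-cosine ramps to avoid spectral splatter. The
  ERS window is placed to coincide exactly with the ERS feature window.
  Because power is amplitude squared, `erd_depth` = 0.5 yields cue-window
  band power at 25 % of baseline.
* **EMG**: a 2-electrode pair in which electrode 1 carries >20 Hz
  band-limited bursts during cues. Burst amplitude per condition is
  √(`emg_percent`/100) × 50 µV so squared-envelope power recovers the
  configured percentage of the actual-movement level; a small noise floor
  (0.5 % of burst RMS) keeps sub-percent conditions recoverable within
  ±20 % relative error.

Default condition profiles: actual/isometric/attempted get strong ERD
(depth 0.5, ERS gain 0.3); imagined gets half that (depth 0.25, gain
0.15), matching the observation that imagined-movement accuracies ran
lower; the no-movement baseline has no modulation. EMG percentages are
100 (actual), ~1 (isometric, attempted), ~0.5 (imagined, none), the
magnitudes reported for the original volunteers. Absolute ERD depths
were never published — only accuracies — so these are plausible
defaults, not fitted values.

Not emulated: eye blinks, line noise, electrode drift and movement
artifacts, inter-channel background correlation, non-stationary rhythm
dynamics, and any realistic volume-conduction forward model. Passing
tests therefore demonstrate correctness of the analysis chain and
recoverability of the assumed signal structure, not expected performance
on real scalp EEG; the near-ceiling synthetic accuracies reflect the
clean default profile.

## Preprocessing

Epochs are cut over the half-open window [−1, 6) s around cue onset
(17500 samples at 2500 Hz); the next cue starts at +7 s, so windows never
overlap. Each channel of each epoch is linearly detrended (least-squares
line removal, idempotent) to suppress DC drift.

The surface Laplacian uses spherical-spline interpolation: with
electrode cosine-angle matrix `cos γᵢⱼ`, the interpolation kernel is

    g(x) = (1/4π) Σ_{n=1}^{N} (2n+1) / (n(n+1))^m · P_n(x)

with stiffness m = 4 and N = 50 Legendre terms, the classical constants
of the method and common practice; a ridge of 1e−5 on the interpolation
matrix guards conditioning. Spline coefficients are solved under the
zero-sum constraint, and the output is the Laplace–Beltrami operator
applied to the interpolant, i.e. the companion kernel with order-(m−1)
weights and a factor −n(n+1) per degree. Consequences verified by tests:
a constant potential maps to zero (the operator is reference-invariant),
and a degree-1 spherical harmonic is reproduced with eigenvalue −2 to
within 0.6 % against a finite-difference oracle. The global 1/r² head
scale is omitted — it cancels in classification. Electrode positions use
an idealized spherical 10/20 construction (Cz at the vertex, midline and
outer-ring electrodes at 18° steps, interior electrodes by great-circle
interpolation), which makes left/right homologs exact mirrors. The
Laplacian is applied to epoched data (it is a per-sample spatial
operator, so this equals filtering the continuous record) and always on
the full 30-channel montage; channel subsets are taken afterwards, so
the 9-channel feature set still benefits from the full-cap filter.

## Features

Welch PSD with Hann-tapered 250 ms windows and 50 % overlap gives exactly
4 Hz resolution; bins 8–24 Hz inclusive are kept (5 bins, so a 3 s
segment averages 23 windows — the segment step is floor(nperseg/2),
i.e. `noverlap = ceil(nperseg/2)`, which reproduces the millisecond
arithmetic (3000−250)/125 + 1 even when nperseg is odd). Density scaling
with Hann power correction is pinned for tests; any fixed convention
cancels in classification. Features are computed separately on the 0–3 s
(ERD) and 3.5–6 s (ERS) slices and ordered (channel, frequency, window).
A log10 transform is applied by default: the original analysis does not
state whether the classifier consumed raw or log power, and log power
conditions the optimizer better; the flag is exposed and tested both
ways. Time-frequency maps reuse the same windowing as a sliding
spectrogram (hop 125 ms, the Welch step, as the original hop is
unreported), average across trials and divide per channel-frequency cell
by its mean over the full −1..6 s epoch, so 1 is average power, <1 is
ERD, >1 is ERS.

EMG processing: bipolar difference of the two EMG electrodes, zero-phase
4th-order Butterworth high-pass at 10 Hz (family and order are this
package's choice; the original reports only "high-pass filtered at
10 Hz"), Hilbert-envelope magnitude, per-trial mean over 0.1–3.5 s. The
per-condition statistic is the squared mean envelope ("power"), as
percentages of the actual-movement condition; a config switch reports
plain magnitude instead, since the original text describes magnitude
averaging while its table is labeled power.

## Classifier

rLLR minimizes `Σ log(1+exp(−yᵢ fᵢ)) + λ‖w‖²` (bias unpenalized) on
internally standardized features, by L-BFGS with a Newton polish to a
gradient infinity-norm below 1e−6; an independent scikit-learn fit of
the same objective agrees to 1e−6 in the tests. λ candidates are
{.001, .01, .1, 1, 10, 100} × total data variance, defined here as the
sum over feature columns of their variance across trials (the original
does not define it); each candidate is scored by stratified ten-fold CV
accuracy and ties go to the stronger penalty. Outer evaluation uses
stratified seeded ten-fold CV. By default λ selection is *nested*
(re-run inside each outer training fold, avoiding selection bias); a
`selection="flat"` mode reproduces the simpler single-grid-search scheme,
since the original wording does not disambiguate the two. Transfer
between conditions fits on all training trials (λ grid-searched the same
way) and evaluates once on the full test set, reusing the training
standardization; test labels are mapped to training classes by their
movement-vs-baseline role.

## Statistics

Per-subject accuracy CIs are exact Clopper–Pearson intervals by default
(beta quantiles); a normal-approximation option exists because the
original per-subject intervals are not uniquely consistent with a single
method and effective n, so no attempt is made to match them. Group
summaries use mean ± t(0.975, n−1)·sd/√n, which exactly reproduces every
published mean-row interval from the printed per-subject accuracies (the
anchor used by the acceptance tests). Display rounding is
nearest-integer, halves away from zero. A permutation module re-runs the
full CV on shuffled labels to verify the 50 % chance level empirically.

## Brain switch

Trial decision values are combined over a sliding window (stride 1) of
`window_trials` consecutive trials — default 8, about one minute at 7 s
per trial — by averaging (a majority-vote mode exists; the original
describes only "combination of multiple classifier predictions"). The
alarm threshold is the smallest value whose exceedance rate on
*calibration* no-movement windows is at or below the target false-alarm
percentage; for a 0 % target it is the null maximum plus 1e−9 of the
score scale. Calibration and evaluation always use disjoint null data
(chronological split) so the reported false-alarm rate is honest. The
published 0 % / 87.5 % operating point was obtained on undeposited human
data with unspecified windowing; it is treated as a qualitative regime
(the acceptance test requires ≥ 75 % mean true positives at a 0 %
calibrated false-alarm target on strong-ERD synthetic sessions), not a
reproduction target.

## Problem sizes and numerical choices

Simulations in the tests, examples and the acceptance script run at
500 Hz — an integer divisor of the 2500 Hz acquisition default chosen so
the 250 ms Welch windows still give exactly 4 Hz bins — with the full
trial design (324/108 trials per session); this keeps a complete
20-subject null calibration within minutes while leaving every count and
window of the design intact. The generator's internal noise synthesis
uses float32 FFTs for speed; recordings are delivered as float64.
Zero-variance feature columns are left unscaled during standardization;
a zero total variance makes all λ candidates equal (the degenerate grid
returns its largest entry, 0). Epoch windows are half-open so sample
counts are exact. The BrainVision reader accepts only the dialect the
writer emits (binary, multiplexed, IEEE float32) and rejects anything
else loudly rather than guessing.

## Known limitations

* Synthetic data only: no artifact model, no subject variability beyond
  the seed, effect sizes assumed rather than fitted; results quantify
  pipeline correctness, not clinical performance.
* The common-spatial-patterns alternative is deliberately not
  implemented (the original comparison found no benefit over the
  Laplacian), and no asynchronous (uncued) detection is attempted.
* Per-subject CI reproduction of the published tables is out of reach in
  principle (method/effective-n underdetermined); group-level intervals
  are the exactly recomputable anchor.
* The spherical-spline Laplacian is accurate for low-degree spatial
  patterns; with electrodes covering only the upper hemisphere, fidelity
  degrades for higher-degree harmonics, as for any scalp montage.
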