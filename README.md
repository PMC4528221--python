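# erdswitch

Detecting *attempted* movement from the EEG when the muscles cannot move.

Patients who become aware during surgery are usually paralyzed by a
neuromuscular blocker: they may try to move, but no movement — and no
signal to the anaesthetist — results. The motor cortex, however, still
produces the classical sensorimotor signature of a movement attempt:
event-related desynchronization (ERD), a power drop of the mu (8–12 Hz)
and beta (18–25 Hz) rhythms during the attempt, followed by event-related
synchronization (ERS), the post-movement beta rebound. A brain–computer
interface that detects this signature can act as a "brain switch" and
raise an alarm.

`erdswitch` is a tested, reusable implementation of that analysis for
researchers in BCI and anaesthesia monitoring. Because the underlying
volunteer data were never deposited, the package ships a first-class
synthetic-data generator that emulates the original study design — cued
sessions of nine 3-second movement trials separated by 4-second silences;
81 trials per condition across four conditions (actual, isometric,
imagined, no movement) before the block, 54 trials per condition
(attempted vs. none) during it — so every stage of the pipeline runs and
is validated end to end without any download.

## The pipeline

1. **Session model / synthetic data** — executable trial plans and
   continuous 30-channel EEG + 2-channel EMG with configurable ERD depth,
   ERS gain and per-condition EMG power (percent of actual movement).
2. **I/O and epoching** — BrainVision (`.vhdr`/`.eeg`/`.vmrk`) writer and
   reader (float32 multiplexed dialect, bit-exact round trip); epochs cut
   over [−1, 6) s around cue onset.
3. **Spatial filtering** — per-trial linear detrend and the
   spherical-spline surface Laplacian with kernel
   `g(cos γ) = (1/4π) Σₙ (2n+1)/(n(n+1))ᵐ Pₙ(cos γ)` (m = 4), evaluated
   through the companion order-(m−1) kernel.
4. **Features** — Welch PSD (Hann, 250 ms windows, 50 % overlap) at
   8, 12, 16, 20, 24 Hz, separately for the ERD (0–3 s) and ERS (3.5–6 s)
   windows: 9 × 5 × 2 = 90 features on the motor channel set
   (C3, C4, Cz, F3, F4, P3, P4, T7, T8), or 300 on all 30 channels.
5. **Classifier** — quadratically regularized linear logistic regression
   (rLLR), minimizing `Σᵢ log(1+exp(−yᵢ(xᵢ·w+b))) + λ‖w‖²`, λ grid-searched
   over `[.001 .01 .1 1 10 100] ×` total data variance with ten-fold
   cross-validation; cross-condition transfer (train on actual movement,
   test on attempted movement) included.
6. **Statistics** — exact binomial CIs per subject, t-based group-mean
   CIs, permutation chance-level checks (two balanced classes ⇒ 50 %).
7. **Brain switch** — consecutive trial decision values averaged over a
   window (default 8 trials ≈ one minute), threshold calibrated on
   held-out no-movement windows for a target false-alarm rate.

## Worked example

`examples/06_crossvalidated_classification.py` simulates four synthetic
subjects (phase-2 design, default strong-ERD profile, 500 Hz) and runs
the full pipeline on the 9-channel motor set:

```
subject 1: accuracy 98 (93–100) % (108 trials)
subject 2: accuracy 99 (95–100) % (108 trials)
subject 3: accuracy 99 (95–100) % (108 trials)
subject 4: accuracy 100 (97–100) % (108 trials)
group mean (95% CI): 99 (98–100) %
```

Each line is a subject's ten-fold cross-validated accuracy over 54
attempted + 54 no-movement trials with its exact binomial 95 % CI; the
last line is the t-based group summary. Lower CI limits above 50 % mean
the attempt is detected above chance. (The synthetic default profile is
deliberately clean; real scalp EEG yields lower numbers.) The remaining
examples cover the session design, the generator and its EMG summary
table, BrainVision round trips, the Laplacian eigenfunction check, the
ERD/ERS time-frequency map, condition transfer, and the brain switch,
e.g. `examples/08_brain_switch.py`:

```
window of 8 trials, threshold -3.126
held-out false alarms: 0.0 %  true positives: 100.0 %
```

A thin CLI wraps the same library calls:

```bash
erdswitch simulate --seed 1 --out sim/              # BrainVision + event TSVs
erdswitch analyze --mode within --channels motor9   # accuracy tables
erdswitch detector --target-fa 0                    # brain-switch report
```

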