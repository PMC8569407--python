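# Methods

## Problem and pipeline

The package classifies short windows of wearable-sensor data into six
physical-activity types — lying, sitting, standing, walking, non-level
walking (uphill/downhill), and running — and measures how well such
classifiers transfer between recording protocols and between age cohorts.
The pipeline is:

1. **Segmentation.** Each placement's 50 Hz tri-axial accelerometer stream is
   cut into overlapping 2 s windows (default step 1 s, i.e. 50 % overlap).
   A window is kept only if it holds ≥ 80 % of the nominal 100 samples
   (`min_fill_frac`); dropouts suppress windows rather than being
   interpolated, because the spectral features need near-complete blocks.
   A window receives the label of the activity covering the largest share of
   its duration, and only if that share is ≥ 80 % (`purity_min`); windows
   spanning activity transitions are discarded so the task stays
   single-label.  The exact overlap fraction and transition handling are
   package conventions — both are configurable.

2. **Features.** 85 named accelerometer features per window, computed from
   the three axes and the total acceleration ‖a‖ treated as a fourth signal:
   mean/SD/range of all four signals (12), pairwise axis correlations (3),
   excess kurtosis, skewness and mean absolute deviation per axis (9),
   10-bin equal-width histograms per axis (30), mean inter-peak interval and
   peak count per axis (6), and per signal the spectral energy, the mean of
   the three dominant (non-DC) frequency bins, their three amplitudes, and
   the integrated periodogram (24), plus the dominant frequency of the total
   acceleration (1).  Two GPS features per window: average haversine speed
   over the window's fixes and the signed last-minus-first elevation
   difference.  The inventory, its naming and its order are a package
   contract (`patd.acc_features.FEATURE_NAMES`).

3. **Models.** Random forests (default 500 trees, √p candidate features per
   split, unlimited depth, fixed seed), either per placement
   (`individual:<position>`, 85 [+2] features) or fused over all five
   placements (`general`), where the five windows sharing a start time are
   concatenated into one 425 [+2] column row.  Concatenation was chosen over
   row-pooling because only concatenation lets trees combine evidence across
   placements.  No class rebalancing is applied; priors follow the window
   counts.

4. **Evaluation.** Leave-one-subject-out (L1SO) cross-validation crossed
   with protocol *scenarios* (train on scripted, combined, or free-living
   data; test on the training composition or on free-living data only) and
   age *designs* (within-old, within-young, young→old, young+old→old).
   Folds always iterate over the *test* cohort; a held-out subject
   contributes no training windows in any cohort or protocol, while
   training-only cohorts are never folded.  Metrics are micro-pooled over
   folds (overall accuracy = trace/total of the pooled confusion matrix;
   per-class precision/recall/F1 in percent with 0-denominator → 0), and
   per-held-out-subject accuracies are retained for distribution summaries.
   The symmetric running↔walking confusion rate,
   100·(n_rw + n_wr)/(n_r + n_w), quantifies cohort differences in
   locomotion confusion.

## Numerical conventions

These must be fixed for the oracle tests to be meaningful:

* SD uses the n−1 denominator; kurtosis/skewness use biased moment
  estimators; zero-variance signals map correlation, kurtosis and skewness
  to 0 so feature vectors stay finite.
* Histogram bins span the window's per-axis [min, max], right-most bin
  closed; a constant axis puts all samples in the first bin.
* A peak is a strict local maximum; peaks closer than 0.2 s are thinned
  keeping the higher (distance filter first), then peaks with topographic
  prominence < 0.05 g are dropped.  Mean inter-peak interval is 0 with
  fewer than two peaks.
* No detrending or tapering before the FFT; the amplitude spectrum is
  |rfft|/n one-sided; dominant frequencies exclude DC and break amplitude
  ties by lower bin index; signal energy is the mean squared amplitude over
  positive frequencies; the integrated one-sided periodogram equals the mean
  squared signal (Parseval), which is how the oracle checks it.  All-zero
  signals yield all-zero spectral features.
* Haversine distances use a 6 371 000 m sphere.  Duplicate accelerometer
  timestamps keep the first sample (with a warning); a median sampling
  interval off by > 10 % from 20 ms warns but does not fail.
* Windows lacking two GPS fixes are invalid for GPS features: GPS-augmented
  tables drop them (counted in the run log); accelerometer-only tables keep
  them.  The elevation difference is signed to preserve uphill/downhill.

## The synthetic cohorts

No public recordings accompany the study design this package implements, so
the `synthetic_data` module generates labeled cohorts whose *structure* —
not whose absolute numbers — matches the phenomena of interest.  Every
numeric default is a package constant, not a measurement.

Signal model per activity: postures are a placement-rotated unit gravity
vector plus Gaussian noise (distinct orientations for lying / sitting /
standing); locomotion adds a harmonic series at a drawn fundamental along
the vertical, lateral sway at the fundamental, and a train of narrow
Gaussian pulses at the gait rate standing in for heel-strike impacts.
Parameters are redrawn every 10 s within an activity bout, so no bout is a
single memorizable tone and within-subject variability is realistic.  Each
subject draws per-activity offsets (gait frequency SD 0.15 Hz, speed SD
0.10 m/s, amplitude scale SD 12 %, posture tilt ≤ 3°).

The encoded contrasts:

* **Age.** Young walking/running fundamentals 1.90/2.90 Hz and speeds
  1.40/3.00 m/s are well separated; old 1.70/1.90 Hz and 1.20/1.80 m/s
  overlap substantially once subject jitter is added (the profile invariant
  `running_walking_overlap(old) > running_walking_overlap(young)` is
  enforced by an overlap-coefficient test).  Old running amplitude (0.36 g)
  sits near old walking (0.30 g), unlike young running (0.90 g).
* **GPS.** Non-level walking is nearly identical to level walking in the
  accelerometer channel (fundamentals 0.02–0.03 Hz apart, same amplitudes
  and noise); it differs through the GPS elevation trend speed × grade
  (grades ~0.10–0.12, random sign) against a small 0.02 m elevation noise.
  This is what makes the GPS features, not the accelerometer, the channel
  that separates the two walking classes.
* **Placements.** A fixed mounting rotation per placement; a dynamic gain
  (knee 1.5 … chest 0.55) on the harmonics; and an impact gain that decays
  up the body (knee 1.0, pocket 0.3, hips 0.2, chest 0.1), so the knee sees
  the gait-impact signature — the strongest running/walking discriminator —
  nearly unfiltered.  The pocket device additionally receives a random
  per-session rotation within 30° of identity, emulating loose pockets.
* **Protocols.** Real-life sessions inflate parameter variances (young ×2.0,
  old ×1.2), encoding that young subjects chose their own environments.

GPS synthesis is local-planar (meters east/north at a fixed reference
latitude converted to degrees), which keeps haversine recovery of configured
speeds testable to within 1 %; horizontal fix noise is 0.1 m so the
path-length inflation bias stays below 1 % at walking speeds.

What the generator does **not** emulate: biomechanical gait detail,
magnetometer/audio channels, GPS multipath and urban canyon effects, sensor
drift, terrain and weather, unscripted activity composition.  Passing the
directional tests therefore shows the *pipeline* extracts and uses the
intended signal structure; it says nothing about absolute accuracies on real
recordings, which is why the published headline accuracies are not
acceptance targets.

## Study configuration of the acceptance checks

The directional reproductions run at desk scale, chosen once: 20 subjects
per cohort (generator seed 2021), the default ~2.5 min two-session schedule
per subject, 100-tree forests, scripted-protocol (S1A) L1SO designs.  The
GPS-contribution check uses five independent 8-subject old cohorts (seeds
101–105) and a sign test (all five gains positive; one-sided p = 1/32);
"largest F1 gains on the walking classes" is asserted as: the class with the
maximum mean F1 gain is level or non-level walking, and both walking-class
gains are positive.  The end-to-end determinism check runs the full
scenario × design grid twice on a compressed 3+3-subject dataset with
10-tree forests and compares summary CSV bytes.  `scripts/acceptance.py`
re-runs the main designs on 12-subject cohorts derived from its `--seed`.

## Known limitations

* The 85-slot spectral inventory is this package's documented resolution of
  a feature list whose published decomposition is not unique; the integrated
  periodogram duplicates information in mean/SD by construction (harmless to
  tree ensembles, declared rather than hidden).
* Published per-participant F1 tables are reproduced from their printed
  precision/recall pairs; three printed rows are internally inconsistent at
  the third decimal (their F1 was evidently computed from unrounded inputs),
  and are checked at the tolerance input rounding permits (±0.015).
* General-scope tables require all five placements to emit a window at the
  same start time; alignment assumes one session clock per subject, which
  the reader and generator guarantee but arbitrary imports may not.
* Between-age designs fit one model per fold only when the held-out subject
  could appear in training; pure-transfer designs reuse a single fit, which
  is an optimization with identical results, not a different design.
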