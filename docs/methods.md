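# Methods

## Problem and pipeline

`imuposture` classifies an infant's static body position — Sitting, Upright,
Supine, Prone, Hands and Knees — from body-worn IMU streams recorded during
caregiver–infant play. Six sensor slots are modelled (two trunk, two leg,
two arm positions), each delivering tri-axial acceleration (m/s²), angular
velocity (rad/s) and magnetic field (arbitrary units) at a nominal 60 Hz
(occasionally 40 Hz). Ground truth comes from an annotation track of
labelled intervals using a 14-position vocabulary; dynamic positions (e.g.
crawling, walking) are folded onto their static counterparts, giving the
five classes. Transition periods between positions carry no label.

The pipeline: preprocessing → clap-based synchronisation → sliding-window
segmentation → feature extraction in five groups → tree-ensemble
classification under infant-grouped cross-validation → importance and
time-in-position reports.

## Preprocessing

- **Gap filling.** Wireless dropouts leave holes in the sample grid. Samples
  are snapped onto a uniform grid at the nominal rate and missing samples
  are filled by cubic-spline interpolation through the observed ones
  (observed samples are never altered). Gaps longer than `max_gap_s`
  (default 1 s) are still filled — downstream filters need a continuous
  series — but flagged in the artefact mask so no window trusts them.
- **Resampling.** 40 Hz streams are polyphase-resampled to 60 Hz (up 3,
  down 2). The per-channel mean is removed before filtering and restored
  afterwards so constants survive the anti-alias filter's passband ripple
  exactly.
- **Artefact masking.** A sensor knocked off and lying still produces a
  physically implausible dead-flat magnitude. The acceleration magnitude's
  sample variance is computed in non-overlapping 0.1-s blocks (6 samples;
  trailing partial block dropped); blocks with variance below 1e-6 are
  masked. The threshold is applied as printed in the protocol, to the
  variance of the magnitude signal in m/s² units. Masking is monotone in
  the threshold and ignores constant offsets.
- **LP/HP decomposition.** Gravity (DC) and movement (AC) parts of the
  acceleration are split with a zero-phase 4th-order Butterworth low-pass at
  1 Hz (both cutoffs default to 1 Hz and are configurable). The high-pass
  part is defined as the residual of the low-pass at the HP cutoff, so when
  the cutoffs coincide the decomposition is exactly complementary
  (`acc_lp + acc_hp == acc_raw`) and DC is removed from the AC part exactly.
  The 1 Hz split is the conventional gravity/movement boundary in
  activity-recognition work; infant play movement occupies roughly 2–15 Hz.
- **Norms and tilt.** Euclidean norms of the raw, LP and HP triples, plus
  accelerometer tilt from the LP (gravity) component under the aerospace
  convention: `roll = atan2(a_y, a_z)`, `pitch = atan2(-a_x, √(a_y²+a_z²))`.
  Tilt is invariant to positive rescaling; zero-norm samples propagate NaN
  and the affected windows are rejected.
- **Synchronisation.** Annotations live on the audio/video clock; the
  caregiver claps five times at task start. Spikes are detected in the
  average of the two caregiver arm-norm channels with a prominence
  threshold of `max(5 × MAD of the baseline-removed signal, 20% of the
  largest prominence present)`. The MAD floor alone admits ordinary
  arm-movement peaks; the relative term works because claps exceed movement
  peaks by an order of magnitude. Detected peaks are matched to annotated
  clap times by the constant offset supported by the most peak/clap pairs
  (tolerance: half the smallest clap spacing, ≤0.5 s); the delay is the
  median of the matched differences, which shrugs off a spurious or missed
  peak. Counts that disagree with the expected five raise a warning, not an
  error.

## Windows and labels

2-s windows advance by 1 s. A window is labelled with a class only if at
least 75% of **all** its samples carry that single annotation — the
denominator includes transition samples, matching the rule that windows
with less than 75% consistent samples stay unassigned, and the boundary is
inclusive (exactly 75% passes; a 50/50 split cannot). Artefact-masked
samples never count toward a class, and windows with more than 25% masked
samples are unassigned outright. Whether transition samples belong in the
denominator was an open choice; counting them is the stricter reading and
makes the rule coincide with the fraction plotted in the windowing figure.

## Feature groups

Per window, five groups over a 20-channel bank per location (raw/LP/HP
acceleration XYZ, gyro XYZ, mag XYZ, three norms, roll, pitch):

- **statistical** (per channel): mean, sd (n−1), median, adjusted
  Fisher–Pearson skewness, bias-corrected excess kurtosis, min, max, and the
  0.25/0.75 quantiles ("key quantiles" default; configurable). Skewness and
  kurtosis of constant windows are 0 by convention so rows stay usable.
- **frequency** (per channel except roll/pitch, which stay time-domain):
  from the one-sided periodogram of the mean-removed, rectangular-windowed
  samples `P(f) = |rfft(x − x̄)|²`: energy `ΣP`, spectral entropy
  `−Σ p ln p` with `p = P/ΣP` (natural log; base 2 configurable), centroid
  `Σ fP/ΣP`, bandwidth `√(Σ(f−centroid)²P/ΣP)`, and the peak frequency
  `argmax_f P`. Constant windows return all five as 0. A Welch estimator is
  available behind the config.
- **summary**: window means of axis sums (x+y+z per location and XYZ
  family) and of location sums (per channel, summed over the sensor set).
- **difference**: window means of axis differences (unordered pairs within
  a family/location) and of location differences (unordered location pairs
  per channel), pair order fixed lexicographically.
- **correlation**: Pearson r for the same axis pairs and location pairs;
  zero-variance pairs are 0 by convention. Cross-modal pairs (e.g.
  acc×gyro) are off by default behind a config flag.

These formulas are normative for the package: the original feature formula
sheet is not available, so the inventory here is a faithful reconstruction
of the five described groups, and an independent brute-force oracle in the
test suite pins every formula to 1e-9.

With the default trunk+legs sensor set this yields 1,480 columns per
window, each tagged (location, signal, group, name).

## Models and evaluation

Folds are built over infants, never windows: infants are shuffled by seed
and dealt round-robin into 5 folds, so all of an infant's sessions sit in
exactly one test fold (the leakage guard). Two families:

- **random forest** (scikit-learn): n_estimators=1000, max_depth=6,
  class_weight='balanced'.
- **gradient-boosted trees** (LightGBM): n_estimators=200, max_depth=6,
  learning_rate=0.1, num_leaves=63, class_weight='balanced',
  feature_fraction=0.5, max_bin=63, deterministic single-thread mode. These
  defaults are the package's own: they keep a 5-fold run on the full
  synthetic benchmark (≈18k windows × 1.5k features) to a few minutes on
  one core while saturating accuracy on separable data; every value is
  overridable per run.

Per class, one-vs-rest F1 = 2PR/(P+R); F1 is 0 when P+R>0 with no true
positives, and recorded as missing (excluded from the across-fold mean)
when the class is absent from the training split or has neither true nor
predicted windows in the test fold — in that last case F1 is 0/0 and
reporting 0 would punish small folds for a definitional artefact. Summaries
report mean ± SE (sd/√k) across folds; confusion matrices report per-cell
mean counts, their SE, and row-normalised percentages.

## Importance analyses

- **Ablation**: retrain with one group kept alone (`only_group`) or removed
  (`without_group`) on identical folds and seed; report
  `ΔF1% = 100·(F1_ablated − F1_all)/F1_all` per class with per-fold values.
  Removing a group with no columns is an exact no-op.
- **|SHAP|**: exact TreeSHAP attributions from the gradient-boosted model's
  native contribution path, absolute values summed over the five class
  outputs (class-symmetric, preserves the partition property), averaged
  over each fold's held-out rows (configurable to training rows), then
  summed and averaged within each (signal × group) cell. Cell sums
  partition the total per-feature sum exactly; cell mean = sum/count by
  construction. Roll and pitch are first-class signals in the grid.
- **Sensor sets**: Trunk vs Trunk+Legs vs Trunk+Legs+Arms on identical
  folds; per class a Friedman test with folds as blocks and sets (optionally
  sets × model families) as treatments, Benjamini–Hochberg adjusted across
  the family of five classes. Fully tied blocks return statistic 0, p = 1.

## Time in position

Per session and class: the temporal sum of windows labelled (and, from the
held-out CV predictions, predicted) as that class, divided by session
duration, ×100. Overlapping windows contribute their 1-s step; the
session's final window contributes its full 2 s, so a fully labelled
session sums to its duration without double-counting overlap (whether the
original analysis counted overlap twice is unstated; this choice keeps
class percentages in [0, 100] and their sum ≤100). Pearson r between
annotated and predicted percentages is computed per class across sessions.

## Synthetic sessions

The simulator emulates the statistical structure the pipeline assumes. A
session is a Markov chain over the five classes (uniform transitions,
log-normal dwells — defaults 10–25 s means, log-sd 0.4, chosen so a 300-s
session holds roughly 10–20 position episodes as in semi-naturalistic play)
separated by 1.5-s unlabelled transition gaps. Per location, each class
fixes a unit gravity direction in the sensor frame (distinct canonical
directions per class, twisted per location); the accelerometer reads
9.81·direction, slerped through gaps, slowly jittered (low-passed
small-angle wander, 0.02 rad), plus band-limited 2–15 Hz movement noise
(0.2–0.5 m/s² by class, 0.6 in transitions) so the frequency features see
energy away from the gravity band. The gyroscope is the angular velocity of
the orientation path plus white noise (0.05 rad/s); the magnetometer is a
fixed world field rotated into the sensor frame plus noise. Sessions
occasionally record at 40 Hz (p=0.1), suffer dropout gaps (p=0.3 per
session, ≤0.5 s), and carry a true annotation delay uniform in ±2 s:
annotation files are written on the audio clock with raw 14-position
labels, and caregiver arm-norm channels carry five clap spikes for the sync
path.

Presets: `separable` (the defaults above), `noisy` (Hands-and-Knees
orientation pulled toward Prone, 3–4× the movement noise and jitter —
mimicking the prone/crawling confusion structure), and `ambiguous_hk`
(4-s Hands-and-Knees dwells, making it the transitional, hard class).

**What passing on synthetic data does and does not show.** The simulator
reproduces the geometry (class-specific gravity orientation), the spectral
split (DC orientation vs band-limited movement), the label structure
(dwells, transitions, sync offset) and the acquisition artefacts (dropouts,
rate switches, dead-flat spans). It does not attempt biomechanically
realistic infant movement, inter-infant postural idiosyncrasy, sensor
migration on clothing, or magnetometer disturbance from the lab
environment. End-to-end recovery on the separable preset therefore
validates the pipeline's plumbing and statistical machinery — not the
field accuracy of the classifier on real infants.

## Numerical conventions

Degenerate inputs are conventions, not errors: constant windows give zero
shape/frequency features, zero-variance correlation pairs give 0, fully
tied Friedman blocks give (0, 1). Modal-label ties below the 75% threshold
are unassigned (two classes cannot tie at ≥75%). All randomness flows from
explicit integer seeds (numpy Generator; LightGBM in deterministic
single-thread mode), and a full pipeline rerun with the same seed
reproduces every CSV byte for byte.

## Problem sizes used in the checks

The bundled benchmark runs 20 infants × 3 sessions × 300 s (≈18k labelled
windows); the sync study uses 100 independent 40-s clap tracks; unit tests
use 6-infant × 60-s datasets. These sizes make the statistical checks
stable while keeping a full run on one core to minutes.

## Known limitations

- The feature inventory reconstructs the five described groups; the exact
  original formula sheet was not available, so per-feature counts (and
  hence sum-|SHAP| magnitudes) need not match the original study's.
- The gradient-boosted family is LightGBM, not CatBoost; ordered boosting
  specifics differ, so only structural properties (not model-specific
  scores) are comparable.
- Tilt angles come from the LP accelerometer alone; no gyro/mag fusion, so
  sustained linear acceleration biases roll/pitch.
- Magnetometer calibration (hard/soft iron) is out of scope; the simulator
  emits an ideal rotated field.
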