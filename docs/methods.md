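# Methods

## Problem and scope

`mibci` implements a three-class motor-imagery (MI) brain-computer
interface pipeline for the hardest common configuration: discriminating
REST from two imagined movements of the *same* limb (hand grasp vs. elbow
flexion), whose cortical representations overlap closely on the
sensorimotor strip. The pipeline classifies 1 s windows of 20-channel,
Cz-referenced EEG with time-domain features — fourth-order autoregressive
(AR) coefficients, root mean square (RMS), and waveform length (WL) — fed
to a one-vs-one (OVO) support-vector machine with a Gaussian kernel. Three
standard comparison extractors (CSP, filter-bank CSP, log band power) run
through the identical classification and evaluation machinery.

Because no public recording of this exact protocol is available, the
package includes a first-class synthetic-EEG generator that reproduces the
protocol (cue structure, trial counts, sampling rate, montage) and the
physiological effect all the feature methods exploit: event-related
desynchronization (ERD) of the mu (8–12 Hz) and beta (18–25 Hz) rhythms.

## Synthetic EEG model

Each channel is a sum of three components, all in microvolts:

* **1/f background** — Gaussian noise spectrally shaped so the power
  spectral density is proportional to 1/f above 1 Hz (flat below), scaled
  to 10 µV RMS. This is the canonical broadband EEG floor.
* **Band-limited oscillators** — Gaussian noise band-passed into the mu
  and beta bands (4th-order Butterworth, forward-backward), scaled to
  5 µV RMS (mu) and 3 µV RMS (beta). These amplitudes put the rhythms at
  roughly half the background RMS, a realistic resting sensorimotor level.
* **Ocular artifacts** — 0.4 s, ~75 µV raised-cosine transients on the
  frontal channels (Fp1/Fp2 full amplitude, F7/F8 half), Poisson-arriving
  at 2/min. Their spectral content sits below 4 Hz, so they exercise the
  claim that 6–35 Hz filtering suppresses ocular contamination.

**Trial protocol.** Four sessions, each a random permutation of 20 trials
per task (REST, MI-GRASP, MI-ELBOW); a trial is a 3 s cue followed by a
uniform 5–7 s rest interval; 2 s of lead-in/lead-out pad each session;
sampling is at 1000 Hz. The default montage is a 20-channel 10–20 subset
containing the sensorimotor sites C3/C4 and their neighbours, referenced
at the vertex.

**ERD.** During the cue window of a given class, the amplitude of a chosen
band oscillator on chosen channels is multiplied by (1 − d), with 200 ms
half-cosine ramps at the window edges to avoid spectral splatter; band
power therefore scales by (1 − d)². The default map attenuates mu and beta
at C3 for MI-GRASP and at C4 for MI-ELBOW, with REST untouched. Real
same-limb imagery is far less lateralized — both tasks project mainly to
the contralateral (left) hemisphere — so this spatial separation is a
deliberate simplification that gives the generator a controllable,
localized class contrast. Depth d is the single dial spanning chance
(d = 0) to high-accuracy (d ≈ 0.6) regimes; no published per-subject ERD
depth exists for this protocol, so the default d = 0.5 was chosen once as
a mid-regime operating point.

**What the generator does not model:** volume conduction and realistic
channel covariance, EMG contamination, non-stationarity across sessions,
subject idiosyncrasy in ERD topography. Passing tests on simulated data
therefore demonstrate the *mechanics* of the pipeline (correct formulas,
leakage-free evaluation, sensible calibration), not expected accuracy on
any human dataset.

All randomness descends from one seed through per-session child
generators, so identical configurations are bit-reproducible.

## Preprocessing

Raw recordings are polyphase-resampled to 250 Hz, band-passed to 6–35 Hz
with a 4th-order Butterworth applied forward-backward (zero phase — the
filter family/order is our choice; zero-phase filtering avoids distorting
mu/beta phase), epoched over 1–3 s after each cue onset, and cut into
non-overlapping 1 s (250-sample) analysis windows. Indices are 0-based
with half-open windows. Filtering precedes epoching for every feature
method. The two windows per epoch double the instance count; windows from
one trial are tracked (`parent_trial`) so that cross-validation never
splits siblings across folds.

## Features

* **Time-domain (per channel, per window):** AR(4) coefficients in the
  prediction convention t_n = Σ a_i t_{n−i}, estimated by Burg's
  forward-backward lattice recursion (stable on 250-sample windows, unlike
  Yule-Walker); RMS; WL = Σ|w_i − w_{i−1}| (N−1 terms). 20 channels × 6 =
  120 features. Constant windows (AR undefined) fall back to AR = 0,
  WL = 0, RMS = |c| with a logged warning.
* **CSP:** one-vs-rest per class; per-trial covariances are
  trace-normalized and class-averaged; the generalized eigenproblem
  C_k v = λ (C_k + C_rest) v yields eigenvalues in (0, 1); the top and
  bottom eigenvector per class give 3 × 2 = 6 filters. Features are the
  log of each filter's output variance normalized by the summed variance
  over the filter set. A diagonal shrinkage of 10⁻⁶ × mean diagonal is
  added when the composite covariance is ill-conditioned.
* **FBCSP:** the same CSP per sub-band (7–15, 15–25, 25–30 Hz),
  concatenated to 18 features.
* **Band power:** log variance of the 8–24 Hz filtered signal per
  channel — 20 features.

CSP-family filters are data-dependent, so during cross-validation they are
refit inside each outer training fold.

## Classification

Three pairwise soft-margin RBF-SVMs (one per unordered class pair), each
trained only on its two classes' rows after per-feature standardization
fit on the training partition. Prediction is max-wins voting; ties go to
the class with the largest summed signed pairwise decision values, then to
the lowest class index. The binary solver is scikit-learn's SVC
(dual-gap tolerance 10⁻³); the OVO decomposition, voting and tie rule are
implemented here.

Hyper-parameters are selected by grid search with inner 10-fold
cross-validation on the outer training partition, over c ∈ (0, 100] and
γ ∈ (0, 3]. The default grid is c ∈ {5, 10, …, 100} and
γ ∈ {0.01, 0.02, 0.05} ∪ {0.1, 0.2, …, 3.0}: with ~120 standardized
features, squared distances between instances are of order the feature
count, so useful kernel widths extend below 0.1; restricting the grid to
γ ≥ 0.1 collapses the kernel toward zero and the classifier toward
majority voting.

Evaluation is 10 × 10 cross-validation (10 repetitions of stratified
10-fold with re-randomized assignment; repetition seeds descend from one
root seed, so reports are bit-reproducible). Stratification is
group-aware at the trial level by default — sibling windows are strongly
autocorrelated, and splitting them across train/test would inflate
accuracy; `group_trials=False` restores plain instance-level
randomization. Whether to standardize is exposed (`standardize`), default
on.

## Evaluation statistics

Discriminability of a feature for a task pair is r², the squared Pearson
correlation between the feature and the 0/1 class indicator (the
BCI-standard two-condition r² statistic). `max_r2_map` reports the full
(electrode, feature) map, per-feature-type maxima and the pooled maximum —
a headline "maximum r² at any electrode" can be quoted either way, so both
are computed. A 200-permutation null for the pooled maximum calibrates it
against selection bias across 120 columns. Confusion matrices accumulate
counts over CV repetitions and report row-normalized rates. Cross-method
comparison summarizes fold accuracies (mean, sd, min, max) and forms
paired per-fold differences with 95% bootstrap confidence intervals —
a deliberately assumption-light alternative to repeated-measures ANOVA.

## Numerical and design notes

* Resampling rejects upsampling; rate ratios must be rational.
* The EDF writer quantizes to 16 bits over a per-channel symmetric
  physical range (quantization error < 0.01 µV at EEG amplitudes) and pads
  the last 1 s record with zeros; reading goes through MNE.
* Grid-search ties resolve to the first cell in row-major order;
  eigenvector signs in CSP follow LAPACK and are not canonicalized (CSP
  features are sign-invariant).
* Degenerate inputs (constant series/columns, single-class fits, empty
  grids, out-of-bounds epochs) raise or warn per the narrowest sensible
  contract; see docstrings.

## Problem sizes used in tests

The acceptance-style checks simulate the full protocol (4 × 20 trials per
task → 240 trials, 480 windows) and evaluate with 2 × 5-fold
cross-validation over a compact grid ({10, 100} × {0.01, 0.05, 0.2},
inner 3-fold), which reproduces the qualitative behaviour of the full
10 × 10 scheme at a fraction of the cost. Unit tests use one short session
(5 trials per task). Measured at these sizes: chance-level accuracy at
d = 0 (≈ 33%), monotone response over d ∈ {0, 0.2, 0.4, 0.6}
(≈ 33/41/62/76%), > 70% at d = 0.6, and an 11-point accuracy spread across
a fixed reference sweep of (c, γ) settings at d = 0.5.

## Known limitations

* Simulated ERD is spatially point-like and temporally stationary within
  the cue; accuracies on simulation say nothing quantitative about human
  data.
* The OVO SVM wraps a library binary solver; margins match the standard
  soft-margin dual to tolerance 10⁻³, not exactly.
* FBCSP uses all 18 features without the mutual-information selection
  stage of the original FBCSP literature (the 18-feature configuration
  uses every sub-band filter).
* Band power for classification uses 8–24 Hz, the same band as the
  topographic discriminability analysis; it is configurable.
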