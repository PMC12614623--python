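# Methods

## Signal model and pipeline

The package analyzes four-class hybrid EEG+fNIRS recordings structured as
24 s task trials.  The processing chain is: band-stop filtering → modified
Beer–Lambert inversion (NIRS) → non-overlapping time-window segmentation →
per-channel features → k-NN under a repeated class-balanced split protocol.
Every stage is deterministic given its inputs; all randomness (generator,
splits, k selection, balancing) derives from explicit integer seeds, with
run *r* of an experiment seeded by `base_seed + r`.

### Beer–Lambert conversion

Optical-density changes ΔB(z, λᵢ) at two wavelengths relate linearly to
oxy-/deoxyhemoglobin concentration changes through the 2×2 extinction matrix
E (1/(mM·cm)), the emitter–detector separation v (cm) and the differential
path-length factor du (dimensionless): the forward model is
ΔB = E·[ΔcO; ΔcD]·v·du and the analysis inverts it per channel and time
point.  Defaults: λ = 760/850 nm with extinction coefficients
(0.1486, 0.3843; 0.2526, 0.1798), v = 3 cm, du = 6 — standard literature
values, all configurable on the `Montage`.  The inversion refuses extinction
matrices with |det| below a configurable epsilon; the forward/inverse pair
is exact to numerical precision (tested to 1e-10 relative error).

### Filtering

Both filters are 2nd-order Butterworth band-stops applied zero-phase
(forward–backward, so the amplitude response is squared and no phase
distortion reaches the envelope features; a strict single-pass mode exists
via `zero_phase=False`).  EEG: 48–53 Hz, targeting 50 Hz line interference.
NIRS: 0.1–5 Hz on the optical densities *before* inversion.  At the NIRS
rate of 10.17 Hz the 5 Hz edge sits within 2% of Nyquist, which is
numerically degenerate; the edge is clipped to 0.98×Nyquist with a warning.
A band-stop at 0.1–5 Hz removes most hemodynamic content; it is implemented
as specified but the filter is configurable and a band-pass alternative
(`kind="band_pass"`) is provided, off by default.  Edge transients are
handled by the reflection padding built into the forward–backward pass.

### Segmentation

Windows of 2.4, 4.8, 12 or 24 s anchored at trial onset; per modality a
window holds floor(window_s × rate) samples and k = floor(duration/window)
windows are taken, discarding trailing samples (at 10.17 Hz and 2.4 s: 24
samples per window, 10 windows, 4 trailing samples of 244 discarded).
EEG and NIRS windows are paired by window index, i.e. by nominal interval.
Segments inherit the trial label and keep the parent trial id so splitting
can avoid trial leakage.

### Features

* **Hilbert envelope (primary).**  The analytic signal is built in the
  frequency domain (zero negative bins, double positive bins, DC/Nyquist
  unchanged — the −i·sign(ω) construction) and the feature is the mean
  modulus over the window: one value per channel, concatenated across
  channels and, for hybrid sets, across modalities (30 + 18 = 48 columns).
  No taper or detrend precedes the construction; edge effects are accepted
  and oracle tests use interior-period tones.  An optional `per_band` mode
  band-passes EEG into delta/theta/alpha/beta first and concatenates the
  four envelopes per channel (NIRS stays broadband — those bands lie above
  its Nyquist).
* **Walsh–Hadamard.**  Mean absolute coefficient of the orthonormal
  transform after zero-padding to a power of two — chosen to mirror the
  "mean magnitude" shape of the envelope feature.
* **Band power.**  Welch PSD (Hann, segment length min(n, 256), 50%
  overlap) integrated over delta (1–4), theta (4–8), alpha (8–13) and beta
  (13–30) Hz for EEG and 0.01–0.2 Hz for hemoglobin signals.  A band
  contributes the bins whose cells overlap it, so the short NIRS windows
  retain a usable (DC-adjacent) band.
* **Statistical moments.**  Mean, population variance, skewness, non-excess
  kurtosis, mean absolute value, RMS; zero-variance windows report
  skewness/kurtosis as 0.

### Classification and evaluation

The k-NN classifier supports Euclidean, city-block, cosine and correlation
distances.  Vote ties are broken by the class of the earliest-ranked
neighbor among the tied classes, then by the smallest class label; neighbor
order under exact distance ties follows training-row order (stable sort).
k is selected per run by 20 stratified 80/20 subsamples of the training set
over odd candidates {1, …, 15}, highest mean validation accuracy, ties to
the smallest k; all candidates are scored on identical splits from a single
neighbor ordering per subsample.  SVM (RBF, C=1), CART and 100-tree random
forest baselines use fixed scikit-learn hyperparameters.

Each of the `n_runs` (default 50) repetitions: down-sample every class to
the minimum class count, split 75/25 per class (exact balance on both
sides), z-score columns on the training rows only, select k, predict, and
score.  Split schemes: `window_random` (default) splits segments freely —
windows of one trial can land on both sides, which leaks trial-level
structure and is flagged here deliberately; `trial_random` keeps all
windows of a trial together; `loso` holds out one subject per run (rotating
over subjects).  Reports carry per-run accuracies, mean ± SD, the pooled
confusion matrix, per-class precision/recall/F1 (zero denominators give 0),
and seeds; modality comparisons use one-way fixed-effects ANOVA on the
per-run accuracies, with no post-hoc correction.

## Synthetic data generator

The generator emulates the acquisition protocol — 6 sessions × 20 trials of
24 s per subject, exactly balanced over the four directions, EEG at 250 Hz
(30 channels) and NIRS at 10.17 Hz (18 channels, 244 samples/trial) — and
only the task epochs; rest and cue phases are not synthesized because the
analysis never consumes them.

Per trial with label c:

* **EEG** = `eeg_effect` · g_c ⊗ sin(2πft + φ) + 1/f noise + white noise +
  50 Hz line noise, with f drawn uniformly in `eeg_band_hz` (default
  8–13 Hz) and random phase per trial.  The class gain vectors g_c default
  to four disjoint contiguous channel groups (gain 1, leak 0.1 elsewhere), a
  stylized direction-dependent topography; they are fully configurable
  (`class_pattern`), and `complementary_class_pattern` builds the
  construction where classes 1–2 are expressed only in EEG and 3–4 only in
  NIRS.
* **NIRS**: HbO = `hemo_effect_mM` · g_c ⊗ (double-gamma HRF ⊛ 24 s task
  boxcar, peak-normalized), HbR = −0.3 · HbO (configurable ratio), rendered
  to optical density at both wavelengths through the forward Beer–Lambert
  model plus white OD noise.  The HRF peaks near 6 s with an undershoot
  near 16 s and is normalized to peak 1.

Default condition parameters: `eeg_effect` 2 µV against 5 µV white + 5 µV
1/f-shaped noise and 5 µV line amplitude — a modest, realistic
effect-to-noise ratio for an oscillatory class signature; `hemo_effect_mM`
1e-3 mM (≈1 µM, a typical task-evoked HbO excursion) against 2e-3 OD noise.

Two numerical choices in the noise model matter and were made for
stationarity and physical plausibility:

* the 1/f component is scaled by its *expected* (Parseval) standard
  deviation, not the realized per-trial one — normalizing each trial's
  realization would couple the windows of a trial (their powers would sum
  to a fixed total) and bias window-level evaluation below chance;
* the 1/f amplitude is flattened below a 1 Hz knee — unbounded 1/f power at
  f→0 is unphysical (EEG acquisition is high-passed), and without the knee
  most noise power lies in periods longer than a window, giving all windows
  of a trial a shared drift that window-level splitting converts into
  trial-identity leakage.

What the generator does **not** emulate: volume conduction and realistic
electrode covariance, photon-transport forward physics, physiological
artifacts (blinks, motion, cardiac/respiratory oscillations),
between-session drift, and subject heterogeneity beyond the seed.  Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline*, not expected accuracy on real recordings.

## Validation conditions

The end-to-end checks run the full 50-repetition protocol at three
conditions: a high-SNR subject (`eeg_effect` 10 µV against 2 µV noise,
`hemo_effect_mM` 5e-3 against 5e-4 OD noise) where the hybrid pipeline must
recover the classes at ≥90% accuracy; a zero-effect construction that must
sit at the 25% chance level; and the complementary-pattern construction
where the hybrid modality must beat each single modality by ≥10 points.

The chance-level check compares the pooled mean accuracy against a 99%
binomial interval with n = test rows × runs.  That interval presumes
independent predictions, but repeated runs on one fixed dataset share its
chance clustering: even with fully i.i.d. features the 50-run mean varies
across datasets by about the interval's width.  The check therefore pools
five independent zero-effect subjects × 10 runs (the same 50 runs and the
same n), which restores the independence the interval assumes.  Problem
sizes throughout the validation (one subject per condition, 2.4 s windows,
1200 segments) are the protocol's own; they keep the whole validation in
the minutes range on a single CPU.

## Known limitations

* The 0.1–5 Hz NIRS band-stop is applied as specified even though it
  removes most of the hemodynamic band; classification on hemoglobin
  features relies on the residual (DC-adjacent and >5 Hz) content unless
  the band-pass alternative is enabled.
* `window_random` splitting leaks within-trial structure whenever signals
  are correlated across a trial's windows; use `trial_random` or `loso` for
  leakage-free estimates.
* The correlation and cosine distances are undefined for constant feature
  rows; inputs are expected to be z-scored (the protocol always does this).
* 12 s and 24 s windows leave at most 2 segments per trial, so balanced
  splitting yields very small test sets; results at those windows are
  reported but noisy.
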