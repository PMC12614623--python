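# hybridbci

A tested, reusable implementation of a hybrid EEG + fNIRS brain-computer
interface (BCI) analysis for a four-class visual paradigm: subjects read text
scrolling **right (1), left (2), up (3) or down (4)** while 30-channel EEG
(250 Hz) and 18-channel two-wavelength NIRS (10.17 Hz) are recorded in 24 s
task trials.  The package is for BCI and neural-signal-processing researchers
who want to study or extend this analysis without access to private
recordings: a first-class synthetic generator reproduces the paradigm's
structure with controllable class effect sizes and noise.

## The analysis

1. **Preprocessing.**  Both modalities are cleaned with 2nd-order Butterworth
   band-stop filters (EEG: 48–53 Hz power-line band; NIRS optical densities:
   0.1–5 Hz), applied zero-phase.  Hemoglobin concentration changes are
   recovered from the two optical-density wavelengths by the modified
   Beer–Lambert law — per channel *z* and time point,

   [ΔcO(z); ΔcD(z)] = (1 / (v·du)) · E⁻¹ · [ΔB(z,λ₁); ΔB(z,λ₂)],

   where E holds the extinction coefficients β_O(λᵢ), β_D(λᵢ), *v* is the
   emitter–detector separation and *du* the differential path-length factor.
2. **Segmentation.**  Each 24 s trial is cut into non-overlapping windows of
   2.4, 4.8, 12 or 24 s that inherit the trial label.
3. **Features.**  The primary feature is the mean modulus of the analytic
   signal per channel per window,

   HTabs = (1/n) Σᵢ √(Re ŷ(tᵢ)² + Im ŷ(tᵢ)²),

   with the imaginary part the Hilbert transform (−i·sign(ω) in frequency).
   Walsh–Hadamard, band-power and statistical-moment baselines are included.
4. **Classification & evaluation.**  k-NN (Euclidean, cosine, city-block or
   correlation distance; k chosen by repeated stratified subsampling of the
   training set), evaluated by 50 repetitions of a class-balanced 75/25
   split, with z-scoring fit on the training rows only.  Reports mean ± SD
   accuracy, pooled confusion matrix, per-class precision/recall/F1, and
   one-way ANOVA across modality sets.  SVM, decision-tree and random-forest
   baselines are available, as are leakage-aware splitting schemes
   (`trial_random`, `loso`) alongside the default window-level split.

## Worked example

```bash
hybridbci simulate --seed 7 --out subject01
hybridbci run --data subject01 --modality eeg+oxy --window 2.4 \
              --feature ht --runs 10 --seed 0 --out report.json
hybridbci report --in report.json
```

prints

```
mean test CA: 88.87% +/- 1.25 over 10 runs
macro F1: 88.87%  precision: 88.91%  recall: 88.87%
pooled confusion (rows=actual, cols=predicted):
     679     20     23     28
      34    655     31     30
      41     23    665     21
      30     23     30    667
```

The simulated subject has 120 balanced trials (6 sessions × 20).  With 2.4 s
windows each trial yields 10 segments (1200 total); every run holds out 75
segments per class, so the pooled confusion matrix counts 10 × 300 = 3000
test predictions.  At the generator's default effect-to-noise ratio the
hybrid EEG+HbO feature set recovers the four directions at ~89% accuracy —
far above the 25% chance level of a balanced four-class problem — and the
accuracy would rise toward 100% as `eeg_effect` grows (see
`docs/methods.md`).  The same pipeline is available as a library:

```python
from hybridbci import RunConfig, run_experiment
from hybridbci.simulate import GeneratorConfig, simulate_subject

ds = simulate_subject(GeneratorConfig(seed=7))
report = run_experiment(ds, RunConfig(modality_set="eeg+oxy", window_s=2.4,
                                      n_runs=10, seed=0))
print(report.mean_ca, report.sd_ca)
```

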