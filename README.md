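# emgfatigue

Muscle fatigue during sustained isometric contraction leaves two robust
signatures in the surface electromyogram (sEMG): the power spectrum
compresses toward lower frequencies (the median frequency MDF falls) and
the signal amplitude grows as motor-unit recruitment compensates for
failing fibres.  `emgfatigue` is a complete, tested pipeline for turning
those signatures into an automatic binary fatigue detector
("easy" vs "difficult" perceived effort):

1. **Simulation** — a seeded generator of fatiguing sEMG trials
   (band-limited Gaussian carrier whose median frequency tracks a
   prescribed decline, linear amplitude growth, 50 Hz powerline
   interference, baseline drift, sensor noise) so every downstream stage
   has controllable ground truth.
2. **Preprocessing** — zero-phase Butterworth band-pass (20–450 Hz),
   50 Hz IIR notch, mean subtraction.
3. **Decomposition** — empirical mode decomposition (EMD) written from
   first principles, plus its noise-assisted ensemble variants EEMD,
   CEEMD, CEEMDAN and ICEEMDAN.  ICEEMDAN extracts mode `k` by averaging
   local means over noise-perturbed copies of the running residual,

       r_k = ⟨ M( r_{k−1} + β_{k−1} E_k(w_i) ) ⟩,   c̃_k = r_{k−1} − r_k,

   which reconstructs the input exactly and suppresses mode mixing.
4. **Features** — per 1 s window and per component: MAV, VAR, RMS, mean
   frequency MF = Σf·P/ΣP, median frequency MPF (half-total-power
   point), instantaneous mean/median frequency summaries from the STFT,
   sample entropy −ln(A/B), and the Hurst exponent from corrected
   rescaled-range analysis.
5. **Embedding** — exact t-SNE (Gaussian affinities with per-point
   perplexity calibration, Student-t low-dimensional kernel, KL-gradient
   descent) reducing the feature table to 3-D.
6. **Classification** — SVM / KNN / ANN with stratified-window and
   grouped-by-subject cross-validation, accuracy
   (TP+TN)/(TP+TN+FP+FN), an IMF-count sweep, and a five-way
   decomposition-method comparison.

## Worked example

```python
import numpy as np
from emgfatigue import (SynthConfig, generate_dataset, preprocess_record,
                        DecompParams, decompose, WindowConfig,
                        extract_feature_table, cross_validate)

cfg = SynthConfig(n_subjects=4, n_trials=2, n_channels=1,
                  duration=20.0, master_seed=0)
records = [preprocess_record(r) for r in generate_dataset(cfg)]

params = DecompParams(variant="ICEEMDAN", ensemble_size=30, seed=0)
imf_sets = {r.key: decompose(r.samples, params) for r in records}
x = records[0].samples
err = np.linalg.norm(x - imf_sets[records[0].key].reconstruct()) / np.linalg.norm(x)
print(f"ICEEMDAN reconstruction error: {err:.2e}")

table = extract_feature_table(records, WindowConfig(), imf_sets, k_keep=5)
report = cross_validate(table, kind="svm", k_folds=5, seed=0)
print(f"windows: {report.config['n_windows']}, "
      f"stratified 5-fold SVM accuracy: {report.mean_accuracy:.3f}")
grouped = cross_validate(table, scheme="grouped-by-subject", k_folds=4,
                         kind="svm", seed=0)
print(f"grouped-by-subject SVM accuracy: {grouped.mean_accuracy:.3f}")
```

prints

```
ICEEMDAN reconstruction error: 1.64e-16
windows: 192, stratified 5-fold SVM accuracy: 0.995
grouped-by-subject SVM accuracy: 0.974
```

The 8 simulated trials yield 192 labelled windows (the first third of
each trial "easy", the last third "difficult").  Reconstruction is exact
to machine precision because the stagewise decomposition telescopes.
Window-level cross-validation is near perfect because windows from the
same trial share folds; the grouped protocol, which holds out whole
subjects, is the honest generalisation estimate and lands slightly
lower.

The same run is available from the shell:

```bash
emgfatigue run config.toml          # full pipeline from a TOML config
emgfatigue validate config.toml     # echo resolved parameters
emgfatigue decompose --variant iceemdan --in rec.csv --out imfs.csv
```

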