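# wheezebench

Benchmarking acoustic features for automatic wheeze detection in
respiratory sounds.

Wheezes — continuous, high-pitched (> 80 ms) adventitious sounds
superimposed on breathing — are a key symptom of asthma and COPD.
Wearable monitors that flag them automatically must run on tight power
budgets, which makes the *choice of feature* matter more than the
classifier: a single cheap, discriminative feature plus a linear
threshold can be preferable to a neural network over a large feature
vector. `wheezebench` implements the full evaluation machinery for this
trade-off study: a bank of 105 acoustic features drawn from the
wheeze-detection literature, a single-feature linear-threshold
classifier with cross-validated threshold selection, a multi-feature
logistic-regression combination search, and a multi-metric ranking
harness — all exercisable end-to-end on a built-in synthetic
respiratory-sound generator, so no clinical recordings are needed to
run, test, or extend it.

## What it computes

Every annotated respiratory event is conditioned (5th-order Butterworth
band-pass 150–2000 Hz → resampling to 8 kHz → peak scaling into
[−1, 1]) and mapped to a 105-dimensional feature vector:

| family | size | examples |
|---|---|---|
| averaged power spectrum | 32 | mean power in 60.9 Hz bands over 0–1950 Hz |
| wavelet (db4, 5 levels) | 20 | per-band \|mean\|, power, SD, adjacent-band ratios |
| MFCC | 13 | DCT of log mel-filterbank energies (26 filters) |
| LPC (order 6) | 8 | a₁..a₆, E⁽⁶⁾, E⁽⁰⁾/E⁽⁴⁾ |
| percentile-frequency ratios | 4 | f₂₅/f₇₅, f₂₅/f₉₀, f₅₀/f₇₅, f₅₀/f₉₀ |
| entropy | 4 | spectral-entropy range/ratio/mean, Rényi (α = 2) |
| misc time/spectral | 24 | tonality index, ASE flux, power ratio, MCI, roll-offs, moments, ZCR, RMS, … |

Features are scaled per Eq. x′ = −1 + 2(x − min)/(max − min) with
min/max taken from the training half of a patient-independent
(recording-level) 50/50 split. Each feature is scored by sweeping a
threshold rule `value ⋛ t`, picking t by stratified five-fold
cross-validation on the training half (objective F1 or Matthews
correlation), and measuring SE/SP/PPV/NPV and the objective on the
held-out half, averaged over repeated random splits. Threshold-free
rankings (ROC/AUC — identical to the Mann–Whitney statistic
U/(n₁n₂) — rank-sum effect size, DBM/OVS distribution separation) and
logistic-regression pair/triple searches with sequential forward
selection complete the harness.

## Worked example

```python
import wheezebench as wb

cfg = wb.SynthConfig(n_recordings=12, events_per_recording=(6, 7),
                     tone_snr_db=0.0, seed=42)
dataset = wb.gen_dataset(cfg)
events = wb.events_from_recordings(dataset.recordings, dataset.annotations)
table = wb.feature_table(events)
print(f"{len(events)} events, {table['label'].eq('wheeze').sum()} wheeze")

y = (table["label"] == "wheeze").to_numpy()
for name in ("tonality_index", "lpc_err_ratio_e0_e4", "rms"):
    v = table[name].to_numpy()
    _, auc = wb.roc_and_auc(v, y)
    eff = wb.ranksum_effect(v[y], v[~y]).effect_size
    print(f"{name:22s} AUC={auc:.3f} effect={eff:.3f}")

report = wb.repeated_evaluation(
    table, wb.EvalConfig(repetitions=10, objective="F1", seed=0),
    features=["tonality_index", "rms", "zcr"])
print(report.table[["SE_mean", "SP_mean", "F1_mean", "threshold_mean", "direction"]].round(3))
```

prints

```
78 events, 47 wheeze
tonality_index         AUC=1.000 effect=1.000
lpc_err_ratio_e0_e4    AUC=1.000 effect=1.000
rms                    AUC=0.894 effect=0.894
                SE_mean  SP_mean  F1_mean  threshold_mean direction
feature
tonality_index    1.000    1.000    1.000          -0.637   greater
zcr               0.723    0.936    0.817           0.546      less
rms               0.796    0.716    0.795          -0.209   greater
```

Even at a 0 dB tone-to-background ratio the MPEG tonality index
separates synthetic wheezes perfectly (AUC = 1.0): its spectral-flatness
basis responds directly to the narrowband component that defines a
wheeze, while level-based features like RMS are weaker and ZCR trades
sensitivity for specificity. The rank-sum effect size equals the
unoriented AUC by the U-statistic identity.

The same pipeline is scriptable from a shell:

```bash
wheezebench simulate --out data/ --seed 1
wheezebench extract  --audio-dir data/ --annotations data/annotations.csv --out features.csv
wheezebench rank     --features features.csv --out reports/
wheezebench evaluate --features features.csv --out reports/ --objective F1 --repetitions 100
```

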