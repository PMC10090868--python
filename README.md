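# ppgsleep

Multi-stage sleep classification from a single overnight finger-PPG channel.

Conventional sleep staging needs full polysomnography — EEG, EOG, EMG, ECG,
airflow and more — scored by an expert in 30 s epochs. `ppgsleep` implements
a single-sensor alternative for researchers working on wearable sleep
monitoring: the photoplethysmogram alone is conditioned, delineated beat by
beat, summarised into a 79-feature bank, screened with nonparametric
statistics, and classified into two (wake/sleep), three (wake/NREM/REM) or
four (wake/LS/DS/REM) stages with classical machine-learning backends.

## Method at a glance

1. **Preprocessing** (per 30 s epoch): baseline-wander removal (two-stage
   moving median, 0.6 s / 1.2 s), Savitzky–Golay smoothing (order 3, frame
   9), z-score normalisation.
2. **Pulse analysis**: systolic peak detection on a 0.5–8 Hz band-passed
   copy; per-beat fiducials (onset, peak, systolic/diastolic inflection,
   end) with systolic/diastolic areas A1, A2 and the ratios
   IPAR = A2/A1, IPTR = T2/T1; the peak-to-peak interval series
   PPI (ms), the amplitude-modulation series RIAM and the instantaneous
   frequency series RIFM = 1000/PPI.
3. **Feature bank** — 79 features in four families:
   - 14 arterial-pressure surrogates: mean and s.d. of A1, A2, A, T1, T2,
     IPAR, IPTR;
   - 18 cardio-respiratory: mean/s.d./SDSD/RMSSD of PPI, RIAM, RIFM;
     pPP50; s.e.m. of PPI; VLF/LF/HF band powers and LF/HF of pulse-rate
     variability (Lomb–Scargle on the uneven PPI series);
   - 25 statistical nonlinear-dynamical descriptors of the PPG waveform
     (absolute-deviation statistics, IQR, central moment, energies, shape
     factor, curve length, Teager energy, robust means, skewness/kurtosis,
     Poincaré SD1/SD2/SD1-SD2 ratio/CCM, Hjorth activity/mobility/
     complexity, Higuchi and Katz fractal dimensions, a Lyapunov
     coefficient);
   - 22 of the same statistics on the PPI series.
4. **Feature selection**: Shapiro–Wilk normality screening motivates the
   nonparametric path; two-class selection keeps features with
   Kruskal–Wallis p < 0.05; multi-class selection scores each feature by

   `sigPair = Σ_pairs 1[p(G_x, G_y) < 0.05]`

   over all class pairs (3 pairs for three-class, 6 for four-class) and
   keeps features with sigPair ≥ 2 (three-class) or ≥ 5 (four-class).
   Feature strength is the Spearman correlation with the ordinal stage
   encoding.
5. **Classification and validation**: random-subspace KNN (data-driven K),
   cubic-polynomial-kernel SVM, and bagged decision trees, evaluated with
   stratified 70/30 splits repeated five times (selection and
   standardisation fit on the training part only), optional 10-fold model
   selection, and a subject-specific within-subject variant.  Metrics:
   accuracy, sensitivity, specificity, precision, an F-score defined as the
   harmonic mean of sensitivity and specificity, and macro one-vs-rest AUC.

A stage-structured synthetic overnight-PPG generator
(`ppgsleep.synthetic`) with known beat-level ground truth makes every
stage of the pipeline testable without recorded data.

## Worked example

```python
import ppgsleep as pps

# one synthetic night: 120 epochs with a bout-structured hypnogram
hyp = pps.random_hypnogram(120, seed=7)
cfg = pps.SyntheticNightConfig(hypnogram=hyp, seed=7)
rec, labels = pps.generate_night(cfg)

from ppgsleep.evaluate import prepare_matrix

feats = pps.extract_night_features(rec, labels)     # 120 x 79 (+ metadata)
df, y = prepare_matrix(feats, "four")
report = pps.select_features(df[list(pps.FEATURE_NAMES)], y, "four")
print(len(report.selected_features))

rep = pps.run_generic_eval(feats, "four", pps.ModelSpec(kind="svm_poly"),
                           repeats=5, seed=7)
print(round(rep.aggregate()["overall_accuracy"]["mean"], 2))
```

Output:

```
65
100.0
```

65 of the 79 features separate at least five of the six stage pairs on
this night, and the cubic SVM stages its epochs at 100% mean accuracy over
five 70/30 splits — perfect because a single synthetic night with the
default presets is separable by construction; on clinical recordings
multi-stage accuracy is substantially lower.

The same steps are available from the shell:

```bash
ppgsleep simulate --epochs 120 --seed 7 --out night.csv --labels hyp.csv
ppgsleep select --in night.csv --labels hyp.csv --scheme four --out sel.csv
ppgsleep run --in night.csv --labels hyp.csv --scheme four --model svm \
             --validation generic --seed 7 --report report.json
```

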