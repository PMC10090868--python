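# Methods

This note documents the models, numerical choices and limitations behind
`ppgsleep`, in the order the pipeline runs.

## Synthetic overnight PPG

The generator is the package's ground-truth instrument: every downstream
stage is validated against the physiology it lays down.

**Beat schedule.** Beats are drawn sequentially across the whole night.
At each beat the active sleep stage is the one scoring the 30 s epoch
containing the beat onset, so stage switches happen mid-stream with no
waveform discontinuity. The instantaneous beat frequency is
`f = (hr_mean/60) · (1 + rifm_depth · sin φ)` where φ is the respiratory
phase, accumulated beat to beat (`φ += 2π · resp_rate · IBI`) so it stays
continuous across stage changes; the inter-beat interval adds Gaussian
jitter with s.d. `hr_sd · 60 / hr_mean²` (the linearised conversion from
beats/min to seconds) and is floored at 0.3 s. Beat amplitude is
`1 + riam_depth · sin φ`.

**Pulse template.** Each beat is the sum of two log-normal-shaped lobes,
`exp(−(ln(t/μ))²/2σ²)`, with the systolic lobe at μ = 0.20·IBI (σ = 0.30)
and the diastolic lobe at μ = 0.58·IBI (σ = 0.25). The diastolic gain is
set from the closed-form lobe area `μσ√(2π)·e^{σ²/2}` so the
diastolic/systolic area ratio equals `ipar_target` exactly. Lobes are
overlap-added over 1.6·IBI. This template gives a visible dicrotic notch
between the lobes, which the fiducial detector relies on.

**Noise.** Baseline wander is a sinusoid (default 0.05 Hz, amplitude 0.3
of the unit pulse) plus an endpoint-detrended random walk at 30% of that
amplitude; white noise is added per sample with the stage's `noise_sd`.

**Stage presets.** The defaults encode textbook sleep physiology as
separable but plausible values: wake has the highest pulse rate
(72 bpm) and variability, deep sleep the lowest rate (55 bpm), the
smallest beat-to-beat jitter (1 bpm) and the deepest, slowest respiratory
amplitude modulation (depth 0.25 at 0.22 Hz), and REM the most irregular
breathing (frequency-modulation depth 0.08 at 0.30 Hz). The
diastolic/systolic area ratio rises from wake (0.45) to deep sleep
(0.65), standing in for the blood-pressure drop of deep sleep. Noise is
2% of pulse amplitude everywhere.

**What it does not emulate** — and hence what passing tests do not show
about recordings: motion artifacts, apneas and arousals, sensor drift and
saturation, inter-subject morphology differences beyond the preset table,
or multi-night variability. The synthetic corpus is intentionally
separable; classifier accuracies on it verify pipeline plumbing, not
clinical performance.

## Preprocessing

Per 30 s epoch, in fixed order: baseline removal → Savitzky–Golay
(order 3, frame 9) → z-score. The full chain is invariant to input scale
and offset. The baseline estimator is a two-stage moving median (0.6 s
then 1.2 s windows, edge-replicated), which attenuates a 0.05 Hz drift by
over 90% while leaving respiratory-band amplitude modulation of the
pulses intact; a zero-phase 4th-order Butterworth high-pass (0.1 Hz) is
selectable. The smoother handles edges by fitting the polynomial on the
truncated terminal window, so polynomials of degree ≤ 3 pass through
unchanged everywhere. Z-scoring uses the sample (n−1) s.d. — as do all
s.d.-type quantities in the package — and maps a constant epoch to zeros.
Normalisation is per-epoch by default (per-recording selectable), since
the aim is removing inter-experimental gain differences.

## Pulse analysis

Peaks: candidates are local maxima of a 0.5–8 Hz band-passed copy with a
300 ms refractory distance; an adaptive threshold keeps candidates whose
prominence exceeds half the 75th percentile of candidate prominences; each
survivor is snapped to the maximum of the original epoch within ±100 ms,
then non-maxima and refractory violations are dropped.

Fiducials: the onset of a beat is the signal minimum between the previous
and current peaks. The systolic/diastolic boundary is resolved in three
tiers: (1) the deepest interior local minimum between peak and beat end
that is followed by a rise of at least 5% of the beat amplitude — the
dicrotic notch proper; (2) failing that, the largest interior maximum of
the second derivative whose curvature returns negative before the beat
end — a shoulder-type notch; (3) failing both (single-lobe beats), a
deterministic split at one third of the beat duration past onset, clipped
to lie past the peak. Tier 1 was adopted after measuring that a
curvature-only rule splits the synthetic two-lobe beat ~0.1 s early and
biases IPAR by ≈ +0.2. Areas are trapezoidal integrals of the beat above
its own minimum, so A1, A2 ≥ 0 and A1 + A2 equals the total beat area
exactly.

Series: PPI_k = (peak_{k+1} − peak_k)·1000/fs ms; RIAM is peak-minus-onset
amplitude (per peak); RIFM = 1000/PPI Hz. Intervals outside 300–2000 ms or
deviating more than 30% from the 5-beat running median are masked and
excluded from PPI-derived features. Epochs with fewer than 4 detected
peaks — or too few plausible intervals for the distribution statistics —
are flagged invalid, carry NaN features and are excluded downstream.

## Feature bank

The canonical catalog is fixed in code: 14 morphological
(means then s.d.s of A1, A2, A, T1, T2, IPAR, IPTR), 18 cardio-respiratory
(mean, s.d., SDSD, RMSSD of PPI/RIAM/RIFM; pPP50; s.e.m. of PPI; VLF, LF,
HF, LF/HF), 25 nonlinear-dynamical on the PPG waveform and 22 on the PPI
series — 79 in total.

Numerical conventions, chosen once and asserted by tests:

- kurtosis is non-excess (normal → 3); skewness/kurtosis are the biased
  standardised moments;
- the n-th central moment defaults to n = 3;
- geometric and harmonic means are computed on |x| + 1e−12 because
  z-scored signals contain non-positive values;
- trimmed means discard 25% (TM25) and 50% (TM50) of total mass
  symmetrically (12.5% and 25% per tail);
- Poincaré descriptors use lag m = 1; CCM is the mean signed area of the
  triangles formed by consecutive return-map triplets, normalised by
  π·SD1·SD2, and 0 by convention when SD1·SD2 = 0;
- Hjorth derivatives are first differences;
- Higuchi FD uses kmax = 10 for 3840-sample epochs (kmax scales down for
  shorter series);
- Katz FD uses amplitude-only path lengths (L = Σ|Δx|, d = max|x−x₀|),
  the variant that is scale-invariant and exactly 1 on monotone lines;
- the Lyapunov coefficient is Rosenstein's largest-exponent estimate with
  embedding dimension 5, delay 4, a Theiler window of (dim−1)·delay+1 and
  the mean log-divergence slope over 10 steps, deterministic given the
  series;
- spectral band powers come from a Lomb–Scargle periodogram of the
  unevenly sampled (beat time, PPI) series, integrated over
  0.003–0.04 / 0.04–0.15 / 0.15–0.4 Hz. A single 30 s epoch cannot
  resolve the VLF band (its period is ~5 minutes); the value is reported
  for catalog completeness and carries little information at this window
  length, which is a known limitation of epoch-level spectral features.

## Feature selection

Shapiro–Wilk normality p-values are computed per feature per class and
logged; they motivate the nonparametric tests but do not gate anything.
Two-class selection keeps features with Kruskal–Wallis p < 0.05.
Multi-class selection tests every class pair with a two-group
Kruskal–Wallis (equivalent to a rank-sum test), unadjusted — matching the
raw p < 0.05 count in the sigPair definition; a Bonferroni-adjusted
variant is available behind `adjust="bonferroni"`. Features are ranked by
descending sigPair with ties broken by ascending mean pairwise p, and
selected at sigPair ≥ 2 (three-class) or ≥ 5 (four-class). Spearman
feature strength uses the ordinal encoding WAKE=0 < LS=1 < DS=2 < REM=3
(configurable). A degenerate zero-variance feature gets r = 0 and a
Kruskal p of 1 (no evidence), with warnings.

## Classification and validation

- Subspace KNN: K is chosen from {3, 5, 7, 10, 15} by hold-out validation
  error on 25% of the training part, then 30 KNN learners are trained on
  random feature subsets of size ⌈d/2⌉ and majority-voted. Distances are
  Minkowski p=3 ("cubic") by default, weighted Euclidean selectable.
- SVM: polynomial kernel of degree 3 (one-vs-one multi-class, one-vs-rest
  decision values for scoring).
- Bagged trees: 100 bootstrap-aggregated decision trees, all features
  available at every split.

Before classification the per-subject linear trend of each feature across
the night is removed, and features are standardised with training-set
statistics inside the model pipeline. Feature selection is fit on the
training partition of each split only and applied unchanged to the test
partition; a dedicated test corrupts test labels and asserts the training
artifacts are byte-identical. The generic protocol is a stratified
70/30 split repeated five times with distinct derived seeds and averaged;
10-fold cross-validated model selection over a ModelSpec grid is
available, with ties resolved toward the simpler model. The
subject-specific protocol repeats a 70/30 split within each subject and
reports per-subject aggregates; single-class subjects are skipped with a
warning.

Metrics follow the one-vs-rest convention: accuracy 100·(TP+TN)/total,
sensitivity 100·TP/(TP+FN), specificity 100·TN/(TN+FP), precision
100·TP/(TP+FP), and an F-score defined as the harmonic mean of
sensitivity and specificity — deliberately not the standard F1 (which is
available via `fscore="f1"`). Multi-class overall accuracy is the
confusion-matrix trace over the total; per-class accuracy is the recall of
that class; AUC is the macro-averaged one-vs-rest area computed from
per-class prediction scores. Zero-denominator ratios are reported
non-finite rather than clamped. No class weighting is applied by default.

## Problem sizes

The shared test corpus is 4 synthetic subjects × 200 epochs (≈ 6.7 h of
signal in total), which gives ≥ 150 epochs per stage — enough for the
between/within-stage effect-size checks and stable 70/30 evaluation while
keeping the default suite fast. `scripts/acceptance.py` uses the same
corpus size. Chance-level (permutation-null) checks rebalance classes by
random subsampling before splitting, since unbalanced shuffled labels
would conflate majority-class priors with chance.

## Known limitations

- The synthetic generator's separability makes classifier accuracies on it
  upper bounds of plumbing correctness, not estimates of clinical skill.
- VLF power from a 30 s window is not physiologically meaningful (above).
- The fiducial detector assumes a single dicrotic notch per beat; severely
  damped or double-notched morphologies fall through to the curvature or
  1/3-split tiers.
- EDF support is read-only via `mne` plus a minimal 16-bit single-channel
  writer used by the simulator; EDF+ annotations are not parsed.
- Hypnogram alias defaults map N1/N2 → light sleep and N3 → deep sleep;
  exports using other scoring conventions must supply an alias table.
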