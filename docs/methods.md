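# Methods

## The analysis in brief

An arterial pulse recording (radial blood-pressure waveform, BPW, or
fingertip photoplethysmogram, PPG; 1024 Hz, ~3 min) is a train of
quasi-periodic beats riding on slow baseline drift.  The pipeline:

1. **Drift removal** — 11th-order Chebyshev type-I high-pass, cutoff
   0.01 Hz.
2. **Beat segmentation** — foot points (diastolic minima at beat onset)
   split the record into half-open per-beat segments `[foot_i, foot_{i+1})`.
3. **Harmonic analysis** — for a beat of k samples,
   `A_n = (2/k) Σ_{s=0}^{k-1} x_s cos(2πns/k)` and `B_n` with sine,
   n = 0…10; `Amp_n = √(A_n²+B_n²)`, `P_n = atan2(B_n, A_n)` in degrees on
   (−180, 180]; amplitude proportions `C_n = Amp_n/Amp_0 × 100 %`.
4. **Windowed variability** — over each beat and its following 14 beats,
   `CV_n = SD(C_n)/mean(C_n) × 100 %` and `P_n_SD = SD(P_n)` (minimal-arc,
   degrees), giving 40 features per pulse:
   `[C_1…C_10, CV_1…CV_10, P_1…P_10, P_1_SD…P_10_SD]`.
5. **Classification** — z-score normalization (fitted on training rows
   only) and an MLP (40 → 20 → 20 → 20 → 1, ReLU, sigmoid output,
   threshold 0.5) under a subject-level protocol: 2:1 train/test split,
   three repeated 80/20 subject splits of the training pool for
   cross-validation, and a single hold-out evaluation.  Metrics: confusion
   matrix, accuracy, sensitivity, specificity, rank-statistic AUC.
6. **Group statistics** — per-index two-tailed t-tests (Welch default),
   significant at p < 0.05, over the 40 indices.

## Numerical conventions

- **Summation limits.** A k-sample period is indexed s = 0…k−1 (half-open
  beats); summing to k would double-count the boundary sample.
- **Phase.** `atan2` resolves the quadrant of `B_n/A_n`; zero-amplitude
  harmonics get `P_n = 0` by convention and are flagged.  Phases are
  reported on (−180, 180].
- **DC term after high-pass filtering.** Filtering removes the beat mean,
  so `Amp_0 = |A_0|` (twice the beat mean) would collapse toward 0 and
  destabilize every `C_n`.  Default `baseline_mode="min_zero"` subtracts
  the beat minimum before the transform, making the DC term twice the
  minimum-to-mean excursion — always positive.  `baseline_mode="none"` is
  exact for unfiltered synthetic beats and is used in round-trip tests.
- **Phase dispersion.** `P_n_SD` re-centers the window's phases on their
  circular mean and wraps deviations to (−180, 180] before the sample SD;
  this equals the linear SD whenever the phases span < 180° and avoids
  spurious dispersion at the branch cut.  An optional percent-of-mean
  reporting mode exists (`phase_sd_relative=True`); degrees is the default.
- **CV with near-zero mean** is undefined; such windows yield NaN for that
  index and the affected rows are dropped (logged in diagnostics).
- **SDs** are sample SDs (ddof = 1) throughout.
- **t-test conventions.** Welch by default (pooled available); two groups
  with zero variance and equal means report t = 0, p = 1.  Phase rows are
  re-centered on the pooled circular mean before testing so groups near
  ±180° are compared on the minimal arc.  No multiple-testing correction
  by default (40 raw tests at α = 0.05); Benjamini–Hochberg optional.

## Filter realization

A direct-form 11th-order filter with normalized cutoff ~2×10⁻⁵ is
numerically unusable; the filter is realized as cascaded second-order
sections (max pole radius 0.9999986, stable).  Application is zero-phase
(`sosfiltfilt`) by default so foot timings are not delayed; attenuation
doubles in dB.  A causal `one_pass` mode (initialized at the signal's
starting level) is provided.  The first and last `transient_s` seconds
(default 5 s) are flagged and beats with feet there are excluded: with
zero-phase application and reflective padding the edge artifacts are
short, while a hard "full settle" rule at this cutoff (hundreds of
seconds) would exclude an entire 3-minute recording.  Note the settling
time also means a 0.005 Hz test tone inside a finite record is removed to
the ~1 % level rather than the steady-state stopband floor (< −100 dB);
tests check the realized transfer function directly.

## Foot detection

Candidate systolic upstrokes are maxima of the first derivative of a
~40 ms Savitzky–Golay-smoothed copy, above 35 % of the derivative's 98th
percentile, separated by at least `min_period_s` (default 0.4 s).  Each
foot is the minimum of the smoothed signal within 0.35 s before its
upstroke, refined by the local minimum of a cubic fit over ±55 samples
(a plain parabolic vertex is biased ~2 samples toward the valley's
shallow side; the cubic term absorbs the asymmetry).  On default-noise
synthetic recordings this recovers ≥ 99 % of ground-truth feet within
±5 samples (≈ 5 ms) with sub-sample mean bias on both channels; any
common residual shift moves `P_n` by the deterministic `n·d/k·360°`
covariance, which cancels in group comparisons.

## The synthetic generator

Each subject has a ten-harmonic template (DC level, amplitude
proportions in % of DC, phases at the foot).  The canonical beat shape is
a periodic sum of von-Mises bumps — systolic peak, dicrotic wave, diastolic
dome, and a localized end-diastolic dip that pins a well-defined minimum
at the beat boundary; its first ten harmonics define the template.  PPG
uses a smoother variant with weaker high-harmonic content.  A recording
concatenates per-beat truncated Fourier series with:

- lognormal multiplicative beat-period jitter (CV 0.03 default; mean
  period 0.85 s, between-subject SD 0.05 s clipped to [0.72, 1.0] s so
  3-minute recordings hold 180–250 beats),
- Gaussian beat-to-beat template jitter (multiplicative on amplitudes,
  CV 0.02; additive on phases, SD = 100×CV degrees),
- a sinusoidal baseline drift (amplitude 5 signal units on a DC of 100,
  0.004 Hz — below the filter cutoff so drift removal is verifiable),
- white sensor noise (SD 1.0, ≈ 0.3 % of the pulse range).

Between-subject template variation is Gaussian per index (amplitude CV
12 % with a 0.05-point floor, phase SD 6°).  No public per-harmonic
population statistics exist for these indices, so these distributions are
plausible placeholders — parameter-recovery and protocol tests quantify
the pipeline against this generator, not against clinical populations.
The generator is phenomenological: no transmission-line hemodynamics, no
ectopy, no motion artifacts beyond drift, and beat-to-beat variation that
is white rather than autonomically structured.  Passing tests therefore
demonstrate correctness of the computation and internal consistency of
the protocol, not clinical performance.

### Group effects

`effect_offsets(d, harmonics)` shifts AD templates' amplitude proportions.
The observable effect is attenuated relative to template units because
the min-zero DC term grows with every harmonic's amplitude: offsets on
the dominant low harmonics mostly cancel inside the `C_n` ratio.  The
default calibrated mode therefore measures, by a Monte-Carlo over the
template distribution with exact noiseless extraction, the realized
between-group separation of extracted `C_n`, and scales the injected
offsets so that separation equals `d` pooled SDs — the effect size is
defined in the space the classifier observes.  Default harmonics are
5–7: their absolute amplitudes are small (weak DC coupling) and elevated
higher-harmonic content is the direction reported for stiffer arteries.
Phases of harmonics ≥ 5 in the canonical template lie near the ±180°
branch cut (their minima align at the foot), so calibrated mode does not
inject phase offsets; the uncalibrated mode shifts both families in
template units.

## Classifier details

sklearn's `MLPClassifier` is driven epoch-by-epoch via `partial_fit` with
an externally seeded shuffle, because its built-in early stopping
re-splits rows at random, which would breach subject-level separation.
Early stopping monitors validation accuracy (patience 20, max 200
epochs) and restores the best weights.  Adam, learning rate 10⁻³, L2
penalty α = 3.0 — with ~50 highly correlated rows per subject and only
tens of subjects, weaker regularization overfits subject idiosyncrasies.
All randomness (splits, folds, weight initialization, shuffling) derives
from one master seed; reruns are bit-identical.  The final model's early
stopping is monitored on an internal 80/20 subject split of the training
pool; held-out subjects are never touched before the single hold-out
evaluation.

## Unit of analysis

Feature rows are pulses (each with its window's variability), so
pulse-level metrics and tests are the default.  Pulse-level t-tests treat
correlated within-subject rows as independent and are anticonservative;
the subject-mean mode (`unit_of_analysis="subject"`) is the calibrated
choice and is what the type-I-error check uses (rejection rate at
α = 0.05 within [0.02, 0.09] under null cohorts).

## Simulation sizes

Protocol-level checks use 30 + 30 subjects; the high-signal run uses
120-s recordings (~90 rows/subject), null and effect-response runs 60-s
recordings.  The statistical-calibration check uses six null cohorts of
10 + 10 subjects with 30-s recordings (240 index comparisons).  Full
3-minute recordings are the generator default and are used for the
beat-count checks.

## Known limitations

- Foot detection is tuned for foot-anchored beat shapes like the
  canonical templates; waveforms whose global minimum sits far from the
  upstroke would need the search window adjusted.
- The min-zero DC convention makes `C_n` depend on beat minimum depth;
  comparisons between pipelines using a different DC convention are not
  unit-compatible.
- Phase features near ±180° are discontinuous in the raw feature table
  (only the windowed dispersion and the t-tests are wrap-aware); a
  template whose phases straddle the cut contributes noisy `P_n` columns.
- With 20 held-out subjects, hold-out metrics have substantial
  cohort-draw variance; seed-averaged results are reported where stability
  matters.
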