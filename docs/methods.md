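# Methods

## Signal model and index definitions

A radial blood-pressure recording is modelled, beat by beat, as ten
harmonics of the beat's own fundamental plus a DC pressure level:

    x(t) = A0 + sum_{n=1..10} A_n cos(2 pi n t / T + phi_n),  t = 0 at the foot.

Per recording, the spectral indices are, for n = 1..10: the amplitude
proportion `Cn` (beat-mean of normalized `A_n`), its beat-to-beat
coefficient of variation `CVn` (sample SD over mean, n−1 convention
throughout), the mean phase angle `Pn` in degrees, and its beat-to-beat
SD `Pn_SD`; `HR_CV` is the CV of instantaneous heart rate 60/RR. That is
40 spectral indices plus one rhythm index.

**Normalization of Cn.** The default divides `A_n` by the DC level `A0`
(the beat's mean raw pressure). Under a sum-to-one convention
(`A_n / sum(A_1..A_10)`, available as `normalization="sum"`, as is
`"fundamental"` = `A_n / A_1`) the ten proportions are constrained, and a
uniform reduction of pulsatile content between groups — the pattern this
analysis targets, in which *every* `Cn` is lower in possible sarcopenia —
cannot be expressed. The DC convention can express it and is therefore
the default. Because detrending removes the DC level, `A0` is measured as
the mean of the raw (pre-detrend) signal over each beat span.

**Phase conventions.** Per-beat phases live in (−pi, pi] with the cosine
convention and t = 0 at the beat onset. Recording-level `Pn` is reported
in [0, 360): foot-referenced pulse harmonics cluster roughly between 60°
and 290°, far from that seam, whereas ±180° would put two of them on the
seam and corrupt between-subject statistics. Across beats, phases are
unwrapped to the running mean (nearest multiple of 2 pi) before the
arithmetic mean and SD; circular moments are deliberately not used, since
the indices are plain means and SDs of angles.

## Conditioning and segmentation

1. **Detrending** subtracts the mean and a zero-phase 4th-order
   Butterworth low-pass (0.3 Hz corner, forward–backward) estimate of the
   baseline drift. The cardiac band 0.5–25 Hz passes with amplitude error
   well under 5% (≈1.7% at 0.5 Hz, <0.01% at 1.2 Hz); respiratory-band
   wander at 0.2 Hz is suppressed to a few percent.
2. **Onset detection** finds maximal-upstroke points as peaks of the
   first difference above an adaptive, scale-free threshold (0.3 × the
   99th percentile), at least half an estimated cardiac period apart (the
   period comes from the periodogram peak in 0.5–3 Hz). Candidate cycles
   whose systolic rise above the preceding minimum level is less than a
   quarter of the signal range are rejected as noise blips. Each onset is
   the **intersecting-tangent foot**: the crossing of the tangent at the
   maximal upstroke (computed on a trace smoothed over ≈4% of a period)
   with the horizontal line through the preceding minimum level. A
   band-limited pulse has a flat foot region whose minimum *position* is
   ill-conditioned; the minimum *level* and the upstroke slope are not,
   which is why the tangent construction is the standard foot definition
   for pressure pulses. First and last partial cycles are dropped.
3. **Segmentation and QC** cuts half-open onset-to-onset slices. A beat
   is rejected when its period deviates more than 30% from the median or
   its correlation with the pointwise-median beat (after length
   normalization) is below 0.8; at least 20 beats must survive. Each
   accepted segment is boundary-conditioned by removing the sawtooth that
   carries the measured discontinuity of its periodic extension (the
   smoothed level at the next onset minus that at this onset). Without
   this, beat-to-beat variability and onset jitter leak the large low
   harmonics into the small high ones, with a dispersion-dependent bias
   that can distort group comparisons of high-harmonic indices.

## Spectral estimation and phase re-referencing

Each beat is resampled to 512 points by Fourier (band-limited)
interpolation — harmonic n then falls exactly on DFT bin n — and
transformed. For an exactly periodic beat the synthesis/analysis round
trip is accurate to machine precision.

Mean phase angles are **re-referenced** per recording: the mean beat is
reconstructed from the across-beat mean amplitudes and phases, its
intersecting-tangent foot is located analytically to sub-sample
precision, and all phases are rotated so that foot is the origin. The
synthetic generator aligns its per-subject profiles with the *same*
functional, so generated truth and extracted phases share one origin by
construction, and integer-sample onset placement cancels out of `Pn`.
The rotation is constant per recording and leaves `Pn_SD` untouched.

Measured recovery against generator ground truth (dispersion-free
subjects): noise-free, `Cn` within 2×10⁻⁵ and `Pn` within 0.03°;
with default noise and wander, cohort-mean errors below 3×10⁻⁵ on `Cn`
and 0.3° on `Pn`. With beat-to-beat dispersion enabled, foot detection on
variable beat morphology carries a small residual time bias (fractions of
a sample); the re-referencing removes its effect on mean phases.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: four
groups of default sizes 74 (robust), 28 (dynapenia), 17 (presarcopenia)
and 14 (sarcopenia); 60-second recordings at 250 Hz; per-group pre-MetS
labels (default fraction 0.45) that drive no waveform effect themselves.

* **Canonical beat**: a stylized radial pulse (fast systolic rise, small
  dicrotic bump, diastolic runoff decaying to the foot) truncated to ten
  harmonics; amplitude ratios decay from A2/A1 ≈ 0.44 to A10/A1 ≈ 0.014,
  DC level 90 and fundamental 15 in arbitrary units (a realistic
  pulsatile-to-mean pressure ratio).
* **Group effect** at `effect_scale` s, severity f ∈ {0, ⅓, ⅔, 1}
  (robust → sarcopenia): harmonic amplitudes × (1 − 0.08·s·f) with the DC
  level fixed (so all DC-normalized `Cn` fall together), phases of
  harmonics 1, 2, 3, 5 − 0.15·s·f rad, and beat-to-beat amplitude CV of
  harmonics 3–10 × (1 + 0.5·s·f). Directions follow the reported group
  contrasts; magnitudes are configuration with these defaults.
* **Between-subject heterogeneity**: log-normal 4% per harmonic
  amplitude, 2% on the DC level (the mean pressure level varies less,
  relatively, than pulsatile amplitudes — and it enters every `Cn`
  denominator coherently), 0.05 rad per phase, 15% on the dispersion
  levels; heart rate N(72, 8) bpm and HR-CV target N(0.04, 0.015). These
  values put the per-index standardized group difference near 1 at
  `effect_scale=1`, so that at the study's group sizes every `Cn`
  separates clearly — the significance structure the configured effect is
  meant to represent. Passing tests therefore show the pipeline detects
  the effects it generates; they cannot certify performance on real
  cohorts, whose heterogeneity and effect sizes are unknown.
* **Beat-to-beat dispersion**: amplitudes are log-normal with the
  log-scale sigma chosen so the realized CV equals `amplitude_cv`
  (positivity plus exact ratio statistics); phases are normal (no
  wrapping at realistic dispersions); per-beat periods are quantized to
  whole samples and returned as the R–R series. Beats are synthesized
  complete; edge truncation is the segmenter's concern.
* **Artifacts**: additive white noise (SD 0.3) and a 0.2 Hz sinusoidal
  baseline wander (amplitude 1.0) exercise the detrending. Not modelled:
  waveform morphology changes with posture/respiration, sensor motion
  artifacts, arrhythmic beats, and any coupling between clinical
  covariates and the waveform beyond group membership.

Determinism: all draws derive from `CohortConfig.seed` through spawned
child streams (one per subject, keyed by a CRC of the subject id), so a
seed reproduces a cohort byte for byte regardless of generation order.

## Statistics and classifiers

Two-group comparisons default to Welch's t-test (safer at 74 vs 59 with
unequal variances); the pooled-variance option exists and satisfies
F = t² against one-way ANOVA on two groups. Four-group comparisons use
one-way ANOVA. Tiers: significant p < 0.05, marginal 0.05 ≤ p < 0.1
(boundary p = 0.05 counts as marginal). No multiple-testing correction by
default, matching per-index reporting practice; Benjamini–Hochberg is
available. Internally constant groups yield p = 1 rather than NaN.

**Bar scoring.** With class-mean bars m_r (robust) and m_s (possible
sarcopenia) and u = clamp((x − m_s)/(m_r − m_s), 0, 1): score1 = 10u,
score2 = 10(1−u). The map is the simplest rule satisfying the defining
properties — scores in [0, 10], score1 + score2 = 10, each class mean a
fixed point scoring 10 on its own bar, both bar orderings handled by the
sign of m_r − m_s — and is pluggable should stepped variants be wanted.
A subject's class is the sign of the mean score difference; an exact tie
goes to the screening-positive class (configurable; screening favours
sensitivity). Evaluation is in-sample by default, mirroring the original
protocol; `cross_validated_scoring` re-selects and re-calibrates inside
each stratified fold. The in-sample estimate is optimistically biased for
a selection-based rule — on null cohorts it sits near 0.6 while the
fold-honest estimate is at chance — so null calibration must use the
cross-validated mode. A fold with no even-marginal index scores its
held-out subjects 0 (no evidence).

**ML harness.** Stratified k-fold (default 3) with a seeded shuffle;
standardization is fit on each training fold only. Fixed hyperparameters:
RBF SVM (C = 1), MLP with one 100-unit hidden layer (max 500 iterations),
Gaussian naive Bayes, CART decision tree, 100-tree random forest,
logistic regression, LDA, and 5-NN. AUC uses the Mann–Whitney rank
statistic (ties ½) on each model's continuous decision score, never on
hard labels. Undefined ratios (empty denominator) are NaN, never 0.
Accuracy is reported in percent; report averages are arithmetic fold
means by construction.

## Problem sizes and numerical choices

Default analyses run one 133-subject cohort in a few seconds on one CPU;
the repeated-cohort checks in the test suite use ten seeded cohorts per
condition. Beat resampling length is 512; beats shorter than 40 samples
raise a resolution error; recordings shorter than 10 s are rejected.
Degenerate inputs (flat signal, all-zero spectra, single-class labels,
empty groups) raise typed exceptions rather than propagating NaN.

## Limitations

* The Cn normalization, the foot convention and the exact geometry of the
  bar-score map are documented choices where the original protocol is
  underspecified; alternatives are switchable but untested against real
  data.
* Synthetic effect magnitudes are configuration. Absolute classifier
  performance on these cohorts (AUC ≈ 0.93–0.98) tracks the chosen
  heterogeneity and should not be read as a clinical estimate.
* Phase indices above harmonic ~7 are sensitive to morphology-dependent
  foot placement on real, noisier data; the re-referencing removes the
  mean error but not the added `Pn_SD` dispersion.
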