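# pulsespec

Harmonic spectral analysis of noninvasive radial blood-pressure waveforms
(BPW) for screening of possible sarcopenia, with a reusable synthetic-cohort
generator standing in for clinical data.

One minute of a radial pressure signal is segmented into single cardiac
cycles at the waveform foot, each beat is expanded in harmonics of its own
fundamental,

&nbsp;&nbsp;&nbsp;&nbsp; x(t) = A₀ + Σₙ₌₁..₁₀ Aₙ cos(2πnt/T + φₙ),

and four index families are aggregated over the beats of a recording
(n = 1…10):

| Index | Meaning |
|---|---|
| Cₙ | amplitude proportion of harmonic n (Aₙ normalized by the DC pressure level A₀; sum- and fundamental-normalized variants available) |
| CVₙ | beat-to-beat coefficient of variation of Cₙ |
| Pₙ | phase angle of harmonic n relative to the beat foot, degrees |
| Pₙ_SD | beat-to-beat SD of Pₙ |

plus HR_CV, the coefficient of variation of instantaneous heart rate
(60/RR) from the R–R series — 41 indices per subject.

On top of the feature extraction the package provides:

* **Group statistics** — per-index Welch/pooled t-tests and one-way ANOVA
  across the robust / dynapenia / presarcopenia / sarcopenia groups, with
  significance tiers (p < 0.05 significant, 0.05 ≤ p < 0.1 marginal).
* **Bar-scoring classifier** — a transparent additive rule: indices that
  separate the classes at least marginally are selected; each is
  calibrated by its two class means ("bars"); a subject scores 0–10 points
  of similarity to each bar per index (score1 + score2 = 10), and the sign
  of the averaged score difference classifies robust vs possible
  sarcopenia. In-sample and fold-honest cross-validated evaluation.
* **ML harness** — eight classifiers (SVM, MLP, GNB, DT, RF, LR, LDA, KNN)
  under stratified threefold cross-validation with per-fold and averaged
  accuracy, sensitivity, specificity and rank-based AUC.
* **Synthetic cohorts** — labeled 1-minute recordings for the four groups
  (default sizes 74/28/17/14) with configurable effect size: affected
  groups have lower harmonic amplitudes, lower low-harmonic phase angles
  and higher beat-to-beat variability, ordered by severity; optional
  pre-MetS labels support the robust+no-MetS subgroup contrast. Every
  recording ships with its generator ground truth.

## Worked example

```python
from pulsespec import CohortConfig, PoolingSpec, generate_cohort, run_cv
from pulsespec.pipeline import feature_matrix, features_table, pool_groups
from pulsespec.scoring import fit_and_score

cohort = generate_cohort(CohortConfig(seed=1))        # 133 subjects, 1 min each
table = features_table(cohort)                        # 41 indices per subject
labels = pool_groups(table, PoolingSpec())            # robust vs pooled possible sarcopenia
x, y = feature_matrix(table.loc[labels.index]), labels.to_numpy()

_, _, report = fit_and_score(x, y)                    # bar-scoring classifier
print(f"scoring: accuracy {100 * report['accuracy']:.1f}%  AUC {report['auc']:.2f}")

lda = next(r for r in run_cv(x, y, k=3, seed=2) if r.method == "LDA")
print(f"LDA 3-fold: accuracy {lda.average_accuracy:.1f}%  AUC {lda.average_auc:.2f}")
```

prints

```
scoring: accuracy 88.7%  AUC 0.95
LDA 3-fold: accuracy 85.8%  AUC 0.92
```

— on this synthetic cohort the configured group effect is detected by both
classifiers well above chance (a null cohort with `effect_scale=0` gives
AUCs near 0.5), with the scoring rule slightly ahead of LDA, the same
ordering reported for the clinical benchmark the harness mirrors.

The same pipeline is scriptable from the shell:

```
pulse generate --out cohort/ --seed 1
pulse features cohort/ --out features.csv
pulse score features.csv --out scores/
pulse run --out run/ --seed 1          # full pipeline with manifest
```

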