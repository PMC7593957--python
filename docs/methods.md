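# Methods

This note records the models, conventions and numerical choices behind
`olivescreen`, and what the synthetic study conditions do and do not show.

## Synthetic fingerprint model

A sample's TIC is

```
intensity(t) = baseline + Σ_k A_k · exp(−(t − rt_k − δ)² / 2σ_k²) + ε(t)
log A_k      = base_k + Σ_attr loading_{k,attr} · median_attr + N(0, amp_log_sd)
```

* **Attributes** are the panel medians (0–10 scale): fruity plus the three
  defect families rancid, fusty-muddy and musty-humid-earthy; a sample
  carries its main perceived defect (and optionally a secondary one, used
  for the fusty+musty QC control). The linear-in-log link makes defect
  intensity act multiplicatively on marker abundance, which is the simplest
  model consistent with defect markers occurring across categories at
  different concentrations.
* **Peak library** (16 compounds): the five suitability standards (hexanal,
  1-hexanol, (Z)-3-hexenyl acetate, (E)-2-heptenal, pentanoic acid) plus
  green esters/alcohols (fruity), oxidation aldehydes and pentanoic acid
  (rancid), fermentative alcohols/acids (fusty-muddy) and C8
  alcohols/guaiacol (musty-humid-earthy). Peaks are Gaussian — no shape
  information is asserted beyond what resolution/SNR arithmetic needs —
  with σ of 0.05–0.10 min, i.e. 2–4 scans at the default grid.
* **Grid**: 5–55 min, 2000 points by default. The full-resolution
  acquisition (~16k points) is one config change; 2000 points keep the
  whole study tractable on a laptop while preserving 2–10-scan peak widths.
* **Drift and noise**: per-batch systematic shifts (deterministic
  alternating pattern, `batch_shift` scans), per-sample Gaussian jitter
  (`rt_jitter_sd` = 2 scans), per-day multiplicative amplitude factor and
  day-level jitter for inter-day work. Detector noise is proportional:
  `sd(t) = cv · max(signal(t), baseline)` with cv = 5% by default, so
  peak-free scans see `cv·baseline` (an additive floor) while gated points
  repeat at the injection CV — this is what makes the per-scan RSD of QC
  replicates concentrate near the injection CV, as a repeatability check
  requires.
* **Population defaults**: 122/108/75 EVOO/VOO/LOO; MPD mix
  0.36/0.50/0.14 (rancid/fusty/musty, the approximate frequencies in the
  study's validation sets); VOO defect medians U(1, 3.5), LOO U(4, 7);
  13% of non-EVOO samples are "boundary" with medians within ±0.5 of the
  VOO/LOO cut at M = 3.5 (the trade convention; configurable). Fruity
  medians: EVOO ~ N(5.0, 0.7), VOO ~ N(2.0, 0.7), LOO ~ U(0, 1);
  biological lognormal spread amp_log_sd = 0.2 per peak. These effect
  sizes are free parameters — there is no public quantitative map from
  sensory medians to VOC concentrations — chosen once so that the default
  population shows *moderate* separation: the full-model cascade defers
  roughly 15% of samples in cross-validation, the regime the screening
  design is meant for. They are not estimates of the real system.

**What the simulator does not emulate**: m/z-resolved structure (TIC only),
co-elution and baseline drift, chemical ageing kinetics, panel noise in the
labels, and the density of a real volatile chromatogram (16 peaks versus
hundreds). Consequences: the noise-gated retained fraction (~16% of scans)
is far below the ~70% seen on real data, and passing tests demonstrate the
*pipeline's* correctness under known ground truth, not field performance.

## Alignment

Interval correlation-optimized shifting: the axis is cut into `n_intervals`
equal contiguous intervals (default 50); each row segment takes the integer
shift in ±`max_shift` (default: 10% of the interval length) maximizing
Pearson correlation with the reference segment (column mean by default);
vacated positions are filled with the nearest retained value. Ties break
toward the smaller |shift|, then the negative one, so output is
deterministic and minimally distorted. Batched data are pre-aligned per
batch against the batch mean, then globally. Because zero shift is always a
candidate and a whole-row guard reverts any row whose full-row correlation
would drop, the mean row correlation to the reference is non-decreasing at
every stage; this is asserted in tests rather than assumed.

## QC and suitability

* Noise: mean/SD of the minimal-variance contiguous window of ≥300 scans —
  an automatic stand-in for "a representative peak-free region".
* Gate: keep scans with mean replicate intensity strictly above
  mean + 3·SD. RSD% = 100·SD(n−1)/mean per retained scan; zero-mean points
  are excluded and logged, not set to 0 or ∞. Summary fractions at the 15%
  and 20% benchmarks.
* SNR = (apex − mean noise)/noise SD, required > 3; resolution
  R = Δt / mean width with width w = 4σ from a local Gaussian fit (baseline
  width convention), required ≥ 1.
* PCA precision check: DModX_i = residual SD of sample i over (p − A)
  degrees of freedom divided by the model's pooled residual SD. The default
  critical value comes from the F distribution at 95%; a fixed override is
  accepted because some softwares plot a normalized statistic against a
  fixed 0.05 line, and the two conventions cannot be reconciled from the
  outside. Data lying numerically in the model plane report DModX = 0.

## Chemometrics conventions

* Autoscaling: column SD with n−1; zero-variance columns get scale 1 and
  centre to exactly 0, keeping the column index aligned with the scan axis
  (columns are never dropped).
* PCA by SVD; Hotelling T² with the F-based limit
  `A(n−1)(n+1)/(n(n−A))·F(A, n−A)`; Q residuals with the
  Jackson–Mudholkar limit; a sample is an outlier when either exceeds its
  limit.
* PLS1-DA by NIPALS with y-deflation; coefficients `b = W(PᵀW)⁻¹q`. At full
  rank this reproduces least squares (tested against the normal equations
  and against an independent PLS implementation).
* Cross-validation: seeded stratified 10-fold ("leave 10% out"); the
  preprocessor is refit inside every fold — held-out rows never touch the
  column statistics (tested by mutation). Q² = 1 − PRESS/TSS with the
  global TSS about the mean of the training dummy; RMSEcv = √(PRESS/n);
  the LV count minimizing RMSEcv wins, ties to fewer LVs (parsimony), max
  10 by default.
* Permutation test (default n = 20): report both the empirical p-value
  (1 + #{permuted Q² ≥ original})/(n + 1) and the strict
  "original exceeds all permuted" flag; the strict flag carries a 1/(n+1)
  false-pass rate on null data by construction.
* CV-ANOVA: F = ((SS_null − PRESS)/LV)/(PRESS/(n − LV − 1)); a model no
  better than the mean clamps F to 0, p to 1.

## Screening decision rules

Uncertainty range: lower = min CV predicted value among true positives,
upper = max among true negatives (the sensitivity = 1 / specificity = 1
points of the ROC). A PV exactly on a threshold is UNCERTAIN — the closed
interval is the conservative choice when the alternative is a forced grade.
When lower > upper the range is empty and the midpoint of the gap is the
single threshold (PV ≥ threshold → positive); the midpoint is this
package's convention, since no published rule defines the printed single
threshold in that case. Samples uncertain at model 1 are not passed to
model 2. Model 2 has its own preprocessor, fitted on the non-EVOO training
subset only. Models failing Q² > 0.4 or CV-ANOVA p < 0.05 are flagged in
their diagnostics but not rejected — the caller decides.

## Evaluation harness

Stratified 80/20 splits with per-category training counts
round-half-up(0.8·n); for post-outlier category sizes 122/108/71 this
reproduces 98/86/57 training and 24/22/14 validation exactly. One master
seed spawns per-split seeds, all recorded for replay. Alignment is fitted
on the full matrix before splitting (as the study workflow does); the
leakage guard therefore covers preprocessing, PLS and thresholds, which is
where leakage would matter. Percentages print at one decimal; 0/0 cells
print blank, never 0. The total correct-of-assigned across splits is the
weighted mean with assigned counts as weights. MPD breakdown counts:
uncertain out of all samples with the defect; correct-as-nonEVOO out of
assigned samples; correct-as-VOO/LOO out of true-VOO/true-LOO samples
reaching a final model-2 call — count pairs "(k/n)" are kept next to every
percentage because the percentages alone are ambiguous at these sample
sizes.

## Problem sizes

The default test and acceptance runs use the full 305-sample population on
the 2000-point grid with seven splits and 20 permutations per model — about
a minute end to end. The 16k-point grid scales linearly and was left out of
the defaults as it adds nothing but resolution to the same synthetic peaks.

## Known limitations

* The sensitivity/specificity = 1 thresholds are order statistics: a single
  atypical training sample widens the reject band. This mirrors the
  design's intent (never misassign a training sample) but makes the
  uncertain rate volatile across splits; the harness reports its SD.
* DModX-based QC cannot flag a gross outlier that dominates the PCA it is
  part of (the outlier becomes a component); the T²/Q screen in the
  chemometrics module is the right tool for that case.
* Inter-day QC repeatability depends on residual sub-scan misalignment
  after integer-shift correction; steep peak flanks inflate RSD there.
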