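# Methods

`trayintake` implements a tray-level analysis of hospital food intake built
around three measurement channels for the same quantity — the grams a
patient consumed from one meal tray:

1. **gold-standard weighing**: every item weighed before and after the meal,
   tare-corrected per container;
2. **nursing dietary diaries**: one routine ordinal score per tray on the
   none / half / all scale (0, 0.5, 1);
3. **image-based (AI) estimation**: per-item mask areas from multiple camera
   views converted to mass by a learned area-to-weight regression.

The package provides the accounting, the agreement statistics that compare
channels 2 and 3 against channel 1, a desk-scale surrogate of the
image-based estimator, and a synthetic cohort generator that reproduces the
statistical structure of the validation study so every stage can be tested
end to end without the (non-deposited) clinical dataset.

## Tray accounting

Intake per item is `(gross_pre − tare) − (gross_post − tare)`; packaged
items are recorded at net weight (tare 0). Items whose post-meal weight
exceeds the pre-meal weight (added liquid, scale drift) are handled by a
configurable negative-intake policy — the default clamps intake to 0 and
counts the event, preserving mass non-negativity without discarding trays.
Nutrients are `intake_g × density/100` from a per-100 g composition table;
tray totals are item sums, so served = intake + leftover holds exactly
under the default policy. Waste is summarised in absolute grams, as each
diet's share of total waste, and per tray served within a diet
(`waste_per_tray_pct`, a diet's waste intensity). Units are grams and kcal
throughout; only lunch and dinner trays are modelled.

## Categorical agreement

Consumed fractions are discretized with fixed thresholds read literally
from the diary scale definition: none = [0, 0.2], half = (0.2, 0.7],
all = (0.7, 1] (the none bin is closed at 0.2; the upper bins are
half-open). Agreement between diary and measured categories is summarised
by the 3×3 concordance matrix, percent agreement (100·trace/n) and Cohen's
kappa, quadratic-weighted (w_ij = 1 − (i−j)²/4) as the ordinal primary
metric and unweighted alongside. The standard error is the
Fleiss–Cohen–Everitt large-sample variance of weighted kappa (the
unweighted case uses identity weights in the same expression); CIs are
kappa ± 1.96·SE truncated to [−1, 1]. If both raters concentrate all mass
in one cell (pe = 1) the result is flagged degenerate and reported as
kappa 1 with a zero-width interval. Trays with zero served weight are
excluded and counted. A sensitivity analysis treats the diary score as a
continuous 0/50/100% proportion and re-discretizes all three streams
through the same mapping.

## Continuous agreement

Signed errors are `estimate − gold` (negative bias = underestimation). The
statistic set: bias (mean), SD of signed errors with the n−1 denominator,
RMSE = √mean(e²) — which forces the identity rmse² = bias² + sd²·(n−1)/n,
used as an internal consistency check — Bland–Altman 95% limits of
agreement bias ± 1.96·sd, P10/P15/P30 (share of estimates within
±10/15/30% of gold, computed over pairs with gold > 0), MAE and MAPE.
Diary scores convert to grams as score × pre-meal served weight. The
default analysis population is trays with non-zero weighed intake
(`nonzero_filter="gold"`), matching the study population for the diary
comparison; the filter is configurable because "non-zero intake" could
also plausibly be defined on the estimate stream.

Confidence intervals are nonparametric percentile bootstrap (default 5000
resamples, seeded, deterministic). Resampling is by tray; because trays
from one patient are correlated, tray-level intervals can be optimistic —
the comparison report carries that caveat explicitly, and a patient-level
cluster bootstrap (`BootstrapConfig(unit="patient")`) is available for
synthetic data, where patient identifiers exist. Resamples on which a
statistic is undefined (e.g. a relative-error metric with no positive gold
values) are dropped; more than 10% of them aborts with a diagnostic error.

## Portion estimation (desk-scale surrogate)

Instance segmentation itself is out of scope (GPU-scale, off-the-shelf
architecture); the pipeline starts from per-view mask areas. Per view,
geometric calibration converts pixels to cm² as the mean over reference
solids (cubes: side²; cylinders: π(d/2)²) of true top-face area over
observed pixel area, making all downstream coefficients
resolution-independent. Mass is predicted per (food class, view) by a
linear model on calibrated area fitted under Smooth L1 loss
(0.5r²/β for |r| < β, |r| − β/2 otherwise; β default 1 g), initialised at
least squares and refined by L-BFGS with the analytic gradient to tight
tolerances — on noiseless data the least-squares point is already exact. A
(class, view) cell with fewer than 5 training pairs falls back to a pooled
fit across that class's views, with a warning.

Multi-view fusion weights each view's prediction by learned reliability ×
observation confidence, renormalised over available views: reliability per
(class, view) is the inverse mean squared validation residual (a small
relative floor guards the noiseless case, where weights become uniform —
harmless since all views then agree). Tray-level consumed mass is
Σ_items max(0, pred_pre − pred_post); an item missing from the post-meal
image counts as fully consumed, matching observed worked-tray rows with
post weight 0. Datasets are split train/val/test at the meal level (all
observations of a tray in one partition) with largest-remainder rounding
of the requested fractions and a seed-stable shuffle. Evaluation reports
item-level MAE and MAPE (over positive true weights) with per-class and
per-view breakdowns, plus segmentation-style pixel accuracy and F1 for
binary mask grids (both-empty convention: 1, flagged).

## Synthetic cohort generator

The generator is the package's study stand-in; its defaults are the study
conditions, and each piece is a documented model:

- **Scale**: 67 patients × Poisson(5.4) trays (min 1) ≈ 362 trays. Five
  items per tray (first course 250±30 g, main 180±25 g, vegetables
  90±15 g, dessert 100±10 g, packaged bread 30±5 g net), mean 650 g
  served — consistent with the study's implied mean served weight
  (total waste / waste fraction / trays). Diet codes are sampled per
  patient at the reported frequencies (remainder split invented).
- **Consumption**: one fraction per tray from the mixture
  0.05·δ₀ + 0.40·δ₁ + 0.55·Beta(2,2), applied item-wise, so post-meal
  weights equal served − consumed exactly and all three diary categories
  are populated. No tray-to-tray appetite trajectory is modelled.
- **Nursing channel**: the true fraction is first discretized on the diary
  thresholds, then the recorded score is drawn from a 3×3 confusion matrix.
  The default rows ([.85,.15,0], [.05,.73,.22], [0,.19,.81]) are
  adjacent-error-only and skewed upward from "half" to "all"; their
  magnitudes were calibrated analytically so the diary-derived gram error
  over trays with non-zero intake averages ≈ +12 g, the reported nursing
  bias, under the default consumption and serving models.
- **AI channel**: estimate = max(0, true + bias + N(0, sd)) per tray, with
  defaults bias −41.1 g and sd 30.9 g (the reported AI error magnitudes);
  clamping events are counted. An additive Gaussian model is the simplest
  one matching a reported (bias, SD) pair; a multiplicative variant is out
  of scope.
- **Mask channel**: per item, view and meal stage, area = weight ×
  area-per-gram × unit-mean lognormal noise. Area-per-gram means are
  per-class (9–20 px/g top view; lateral views at 0.6× for
  foreshortening). The CV defaults (0.25 top, 0.42 lateral) were
  Monte-Carlo-calibrated so the fitted pipeline's tray-level MAE lands
  near one tenth of the mean tray weight, the reported real-world
  performance level; a first closed-form calibration was revised because
  it neglected the errors-in-variables inflation of regression error
  under multiplicative area noise. Confidence is 1.0 for generated masks.

One RNG stream per concern (structure, serving, consumption, nursing, AI,
masks), each seeded as `default_rng([seed, offset])` with a fixed offset,
so identical configs are bit-reproducible and extending one channel never
perturbs another.

What the generator does **not** emulate: real mask segmentation failures
(occlusion, class confusion), texture-modified-food effects, within-patient
appetite correlation beyond the shared diet code, liquid items, breakfast
trays, and the real study's AI-subset selection rule (n = 23). Passing
tests therefore demonstrate correctness of the statistical machinery under
the assumed error models, not clinical performance of any real AI system.

## Numerical choices and degenerate inputs

- SD uses the n−1 denominator (required for the RMSE identity to reproduce
  published triples); LoA use z = 1.96 exactly.
- Category thresholds are closed/half-open exactly as defined; `categorize`
  is monotone by construction.
- Bootstrap intervals are percentile (no BCa); identical seeds give
  identical intervals.
- Negative AI estimates and mask areas are clamped at 0 (masses and areas
  are non-negative); clamps are counted, never silent.
- Zero-served trays raise or are excluded-with-count depending on the
  stage; all-zero-gold samples make relative metrics an explicit error.
- Smooth-L1 fitting is deterministic (no stochastic optimiser); fusion
  weights renormalise over available views, so a singleton view reduces to
  its single-view prediction.

## Known limitations

- Patient-level inference: tray-level bootstrap CIs ignore within-patient
  correlation. The cluster bootstrap hook exists but is validated only on
  synthetic data; the real study could not link trays to patients at all.
- The published headline numbers that depend on the unavailable clinical
  dataset (60.8% concordance, κw = 0.49, the P10/P15/P30 column, 72.1 kg /
  30.7% waste) are generator-calibration references, not reproduction
  targets; the package reproduces the analytic identities and recovers its
  own configured error models instead.
- The area-to-weight head is linear per class; nonlinear regression heads,
  depth/3-D reconstruction and pixel-level segmentation are out of scope.

## Problem sizes used in tests

Unit tests run on cohorts of ~100–350 trays; channel-recovery and
acceptance checks use ~5000 trays (1000 patients × 5); bootstrap coverage
uses 500 replicate datasets of n = 100 with 2000 resamples; the portion
pipeline is exercised on ~250-tray cohorts with four views. These sizes
give Monte-Carlo standard errors comfortably inside the asserted
tolerances while keeping the full suite under a minute.
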