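# Methods

This note records the modeling conventions, numerical choices and
known limitations of `driftgbm`, in the spirit of a statistical
software methods appendix.

## KDIGO staging conventions

Staging works on daily-aggregated SCr series (integer day offsets from
admission; "48 hours" is the trailing 2-day window, "7 days" the
trailing 7-day window on that grid).

- **Baseline creatinine** is the most recent pre-admission value
  within a lookback window (default 365 days, configurable), otherwise
  the admission (day 0) value. The baseline is fixed for the whole
  stay; rolling in-stay baselines are not used.
- **Ratio criteria** (≥ 1.5×, ≥ 2.0×, ≥ 3.0× baseline) compare each
  day's value against this fixed baseline. The printed stage bands
  (1.5–1.9, 2.0–2.9) are implemented as half-open thresholds — a ratio
  of 1.95 is stage 1, not unstaged — and because the reference is the
  fixed admission-era baseline, the ratio rule can fire on any stay
  day rather than only within a literal 7-day window; with negatives
  censored at day 7 this distinction is immaterial in practice.
- **The 48-hour delta criterion** is an increase *by* ≥ 0.3 mg/dL
  relative to the minimum value in the trailing 2-day window
  (including pre-admission values that fall inside the window). The
  alternative literal reading, an increase *to* 0.3 mg/dL, is not
  clinically meaningful.
- **Stage 3 absolute rule**: SCr ≥ 4.0 mg/dL qualifies only together
  with an acute ≥ 0.3 mg/dL rise within 48 h, so chronically elevated
  creatinine does not stage. Any RRT day is stage 3, with or without a
  measurement that day.
- Stages are cumulative; events report the first day each level is
  reached. Threshold comparisons carry a 1e-9 slack so representation
  noise on exactly-threshold values cannot flip a stage.
- Urine-output criteria are out of scope (unreliable outside critical
  care).

## Discrete-time sampling

A stay is divided into windows at times Δt, 2Δt, …; the sample at
window *t* uses records up to and including day *t* − Δt and predicts
onset at *t*. Conventions:

- Onset days that fall off the Δt grid are assigned to the smallest
  grid time ≥ onset; events are never dropped.
- The onset window is the single positive; windows after it are
  excluded (post-onset). For tasks with stage threshold > 1, windows
  at or after a lower-stage onset but before the task-stage onset are
  excluded (between-stages): once a milder AKI stage has begun, the
  task-stage status of subsequent days is not adjudicable because
  clinicians may have intervened.
- Negative windows beyond the censor day (default *T* = 7) are
  excluded (post-censor) to limit class imbalance; this applies also
  to pre-onset windows of late-onset encounters, while the positive
  window itself is always retained. Excluded windows are materialized
  with reasons and audited per encounter rather than silently dropped.
- The feature builder reports the latest record day it consumed for
  every emitted row; the assembler raises a hard error if that ever
  exceeds *t* − Δt. Leakage is a bug, not a warning.

Task presets mirror the study design: any-AKI with a 48-hour window
(Δt = 2), stage ≥ 2 and stage 3 with 24-hour windows (Δt = 1).

## Feature pipeline

The fitted `FeatureScheme` is the transferable state: per-feature
1st/99th percentile cutpoints (pooled over all development records,
linear interpolation), categorical vocabularies, medication and
procedure lists, and the exclusion list. Values outside the cutpoints
are *removed* (set missing) rather than clipped — the GBM handles
missingness natively — and sample-and-hold then falls back to the last
earlier valid value (unlimited horizon by default, configurable).
Unseen categories under a transferred scheme map to all-zero one-hot
blocks so the source model's input space stays fixed. The
blood-pressure trend is the least-squares slope through the last ≤ 3
daily systolic values (two values: their difference; fewer: 0).

All serum-creatinine and blood-urea-nitrogen forms are excluded as
predictors, and additionally renal replacement therapy codes: RRT
initiation is itself a stage-3 criterion, so admitting it as a feature
would leak the outcome into the severe-AKI task.

## TransferGBM

Base learner is XGBoost (`binary:logistic`, `hist`, single thread,
fixed seeds; missing values native). Choices that matter:

- **Source fit**: candidate hyperparameters are sampled from the
  printed ranges (default 25 draws; an explicit candidate list is
  searched exhaustively) and scored by mean stratified k-fold CV AUROC
  with per-fold early stopping (fold count configurable, 10 by
  default). The final tree count is the rounded mean of the per-fold
  early-stopped counts, refitted on all development data.
- **Adaptation** continues boosting from a *copy* of the source
  booster on the target development matrix projected into the source
  input space, for up to the source's own tree count (a symmetric
  budget), early-stopped. The booster is always cut back to its best
  iteration but never below the inherited source trees, so
  `n_new_rounds=0` is exactly the source model.
- **Early-stopping holdout**: models fitted outside CV use a
  stratified 20% holdout. At the cohort sizes used here a smaller
  holdout retains too few positive windows for a stable stopping
  decision, which made refits erratic.
- **Stacking** defaults to out-of-fold (k = 5): both base models are
  re-derived per fold so the meta-learner never sees an in-sample
  probability. The `faithful` mode reproduces the original in-sample
  recipe and is retained for comparability.
- **Meta-learner**: logistic regression on the two raw probabilities
  with light L2 regularization (C = 10), which keeps coefficients
  finite on separable stacking matrices without perturbing the AUROC
  ranking.
- No class weighting or resampling anywhere, matching the deliberately
  plain modeling pipeline of the study design.
- Provenance: every model records a SHA-256 fingerprint of its
  training matrix; the transported path re-exposes the source
  fingerprint, which proves it never saw target data.

## Synthetic cohort generator

The simulator emulates an eight-year inpatient population (2010–2017)
with the study cohort's published structure: yearly sizes from ~15k to
~20k encounters, any-AKI prevalence declining 16.9% → 12.8%, an aging
age-band mix, a fixed race/sex mix, and a stage mix of roughly
86/8/6% (stage-1-only / max-stage-2 / stage-3) among AKI encounters.

- **Outcome model**: encounter-level covariates *z* (10 standardized
  labs, age band, one medication exposure) enter a logistic risk
  σ(a_y + β_y·z + ε), ε ~ N(0, noise_sd), with ‖β‖ = 1.6 and
  noise_sd = 0.3 by default — this yields encounter-level oracle AUROC
  ≈ 0.82, in the range reported for tabular AKI models. The intercept
  a_y is solved each year (Brent's method) so the mean risk equals the
  scheduled prevalence; the empirical prevalence is then binomial
  around the schedule.
- **Concept drift** rotates β in consecutive coordinate planes by
  `concept_drift_rate` radians per elapsed year (norm-preserving, so
  attainable discrimination is constant while the transported model's
  knowledge decays smoothly). An optional
  `rerandomize_from_year` replaces β with an independent same-norm
  vector from that year on — an abrupt, complete concept change.
- **Covariate shift** displaces each numeric feature's latent mean by
  `covariate_shift_rate` standard deviations per year in a fixed
  per-feature direction, and tilts categorical mixes.
- **Feature-space growth**: each feature has a birth year and is
  structurally absent (not merely unmeasured) before it; the default
  scenario introduces two labs in 2014, exercising the common/unique
  feature split.
- **SCr trajectories** are built to round-trip exactly through the
  KDIGO labeler. Baselines are drawn in [0.6, 1.3] mg/dL; non-AKI (and
  pre-onset) days fluctuate within ±10% of baseline, which with that
  baseline range can never reach a 1.5 ratio or a 0.3 mg/dL 48-hour
  rise. AKI encounters climb a piecewise-linear ladder (ratios 1.6 and
  2.4 on the one or two days before onset for stages 2 and 3) to a
  peak drawn strictly inside the designated stage's ratio band —
  inset by 0.05 so the 4-decimal rounding of stored values can never
  cross a threshold — on the onset day, then decay linearly toward
  baseline. A quarter of stage-3 encounters instead peak in the
  stage-2 band and qualify through an RRT day at onset. Onset days are
  uniform over stay days 1–10, so some positives fall past the censor
  day.
- **Length of stay** is zero-truncated negative binomial with mean ≈ 6
  days (dispersion 2), allowing stays on both sides of the censor
  point.
- All randomness flows from a single seed through named
  `numpy.random.Generator` substreams per (year, component);
  structural draws (feature scales, coefficient directions) depend on
  the config seed only, so they are shared across years.

What the simulator does **not** emulate: real clinical vocabularies
(codes are opaque tokens), intra-day dynamics, physiological coupling
between features and creatinine beyond the latent risk, informative
missingness, or readmission structure. Passing tests therefore
demonstrate the *mechanics* of drift correction — not clinical
performance on real EHR data, which has no synthetic stand-in here.

## Evaluation design

- Development/validation splits (80/20) and training-fraction
  subsamples are stratified at the **encounter** level, keeping all of
  a stay's windows on one side so no encounter straddles the split.
  Subsampling is nested per seed (the 25% set is contained in the 50%
  set, …), emulating data accumulation.
- AUROC is the rank statistic (ties ½); CIs are stratified percentile
  bootstrap over validation windows (B = 1000 by default; the
  bootstrap mean is reported alongside the plug-in estimate), with an
  analytic DeLong interval available as a deterministic alternative.
  Window-level resampling is the default; the bootstrap is seeded.
- The drift summary is ΔAUROC = refitted (internal validation) −
  transported (temporal validation) per target year at full training
  fraction.
- `ExperimentConfig` defaults to 5 CV folds and 8 hyperparameter
  draws; the full 10-fold/25-draw search remains available via
  `fit_source` and is worth it at real-data scale.

## Test-scenario sizes

The stochastic regime properties are established as seed averages at
deliberately reduced cohort sizes: ensemble dominance on the
moderate-drift scenario (rotation 0.15 rad/yr, shift 0.05 sd/yr) with
1,500 encounters/year over 20 seeds at training fractions 25% and
100%; degradation regimes (zero drift; re-randomized coefficients) at
1,000 encounters/year over 10 seeds, compared as mean AUROC
differences; the refit-gain trend under strong rotation
(0.35 rad/yr) at 800 encounters/year over 20 seeds. Single-seed
differences at these sizes carry sampling noise of a few hundredths of
AUROC; the averages are the meaningful quantities.

## Known limitations

- Window-level AUROC is intrinsically below the encounter-level oracle
  because the simulated risk is constant within a stay while labels
  are day-specific; timing is unlearnable by design.
- The adaptation budget (source tree count) and the meta-learner's
  regularization are sensible defaults, not tuned optima.
- Instance-weighting transfer (TrAdaBoost-style), deep/sequence
  models, recalibration-only updating, calibration metrics and drift
  *detection* are out of scope.
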