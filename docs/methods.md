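# Methods

This note documents the models, conventions and design choices behind
`ppgr`: what the synthetic cohort generator emulates, how the 2-h iAUC
target and every feature are defined, how the predictive models are
evaluated, and where the method has known, quantified limitations.

## 1. Synthetic cohort generator

Real cohorts pairing CGM traces with annotated meal logs contain
personal data and are not distributable, so the pipeline ships a
generator whose every knob is explicit (`SimulationConfig`) and whose
per-meal ground truth is retained, making every downstream stage
testable against analytic expectations.

### Structural meal-response model

A meal with carbohydrate/fat/protein grams (C, F, P), eaten by a
participant with sensitivity *s* at hour-of-day *h*, has true 2-h
incremental area

  T = s · m(h) · max(0, β₀ + β_C·C + β_F·F + β_P·P)

with defaults β_C = +1.08, β_F = −1.54, β_P = −3.27 mmol·min/L per gram
(population-scale effect sizes reported for cohorts of this design),
β₀ = 80 mmol·min/L, circadian multiplier m(h) = max(0, 1 + g·(h−7)/12)
with slope g = 0.15, and s log-normal with SD(log s) = 0.3. The linear
form is deliberately simple: it makes OLS recovery of the βs a
well-posed end-to-end test, and the max(0,·) floor encodes that a meal
cannot produce negative incremental area.

### Trace rendering

Each participant's trace is a personal baseline level
(~N(5.5, 0.4²) mmol/L) plus a slow mean-reverting AR(1) wiggle
(stationary SD 0.2 mmol/L, 3-h timescale), plus one response bump per
meal, plus sensor noise N(0, 0.25²), quantized to 0.1 mmol/L, sampled
on the 15-min grid and clipped to [2, 30] mmol/L.

The bump is h(u) = (u·e^(1−u))², u = (t − t_meal)/τ — a squared-gamma
shape with unit peak at u = 1. Two properties matter. Its onset is
lagged (h′(0) = 0), matching the delayed start of real postprandial
excursions; a bump that rises at full slope from the first instant
leaks into the pre-meal baseline-search window and drags the detected
baseline systematically early, which measurably attenuates every
downstream effect estimate. And its 2-h integral has a closed form, so
the amplitude is set exactly such that the noiseless bump area over
[t_meal, t_meal + 2 h] equals the meal's true T. Time-to-peak defaults
to τ = 35 min for solid meals and 25 min for drinks (interstitial
sensors peak ~30–60 min after a meal; the value is chosen near the low
end so that the ≤15-min grid offset of the anchored window keeps
discretization losses inside the 5% tolerance the pipeline-consistency
check budgets for).

Meals are drawn at jittered conventional hours (~07:30, 12:30, 19:00);
compositions are log-normal — carbs LN(ln 80, 0.22), fat LN(ln 5,
0.35), protein LN(ln 7, 0.30), fiber LN(ln 3, 0.4) grams — chosen once
as plausible for merged main meals and, importantly, such that the
linear response is almost surely positive even at β₀ = 0, so the
truncation floor stays out of parameter-recovery experiments. These
distributions are generator conveniences, not estimates of any real
cohort. Standardized breakfasts run on days 2–7 (bread, bread+butter,
glucose drink; all ~50 g carbohydrate).

**Logging delay.** Each meal's logged timestamp trails its
physiological start by Uniform(0, 15) min. This is the phenomenon the
backward minimum search exists to correct, and simulating it is
essential: without it the baseline anchor can only ever sit at or
before the true meal start, turning the anchor-time jitter into a
one-sided loss of late excursion area.

**Missingness.** Single samples drop out at rate 0.02; long outages of
60–240 min arrive at 0.5 per participant-week. Coverage of the side
tables is partial by design (microbiome 85%, activity 70%), so the
ablation's row-count bookkeeping is exercised. The microbiome table is
drawn independently of everything else unless `microbiome_effect` > 0
couples its first coordinate to log-sensitivity; the default 0 makes
"microbiome adds nothing" a ground-truth property the model comparison
should — and does — recover.

### What the generator does not emulate

Food-recognition/annotation error, barcode foods, micronutrients beyond
fiber, sensor calibration drift, day-to-day sensitivity fluctuation
within a person, meal skipping, and any real microbiome–phenotype
coupling. Passing tests therefore demonstrate the *pipeline's*
correctness and the *recoverability* of the generator's structure, not
real-world predictive performance; headline R values on synthetic data
are upper bounds set by the generator's noise, not estimates for any
real cohort.

## 2. Target and glycemic features

* **Gap filling** — consecutive samples 15–30 min apart are bridged by
  one midpoint sample with the mean value; longer gaps are recorded and
  any window they touch excludes that meal.
* **Baseline** — among samples in [t_meal − 30 min, t_meal], the local
  minimum (≤ both in-window neighbours, edges one-sided) closest to the
  meal; ties toward the meal; monotone windows fall back to the window
  minimum. The 30-min search width is the default; 15/45/60-min
  variants are exposed for sensitivity analysis.
* **iAUC** — positive-part trapezoid over [baseline time, +2 h],
  baseline crossings interpolated ("cut" convention), window endpoints
  interpolated onto the boundaries. Anchoring at the baseline time
  rather than the logged time is deliberate: with delayed logging the
  baseline time is the better estimate of the excursion start.
* **Trends** — OLS slope of glucose vs time over the prior 1/2/4 h
  (≥ 2 samples; a two-point difference was rejected as noise-sensitive).
* **Past iAUCs** — same integral over the prior 1/2/4 h with baseline =
  window minimum (a convention; the literature does not fix one).
* **`glucose_at_meal`** — the interpolated reading at the logged
  mealtime; this, not the searched baseline value, is the "glucose
  baseline" feature in G, though both are emitted.

## 3. Cumulative glycemic metrics

For study day d ≥ 2, every metric uses all samples strictly before day
d's midnight — only past information, joinable to that day's meals.
Conventions: MAGE uses a 1×sample-SD threshold, raw-series turning
points including endpoints, both directions averaged, empty set → 0
(deliberately simpler than smoothing-based variants; the divergence is
documented). CONGA(lag) is the SD (ddof 1) of differences between
samples exactly lag apart, matched on-grid ±1 min. LBGI/HBGI use the
log-power risk transform f(g) = 1.509((ln g)^1.084 − 5.381) on mg/dL
(× 18.016); note the transform's zero sits at 112.5 mg/dL = 6.244
mmol/L, so a constant 6.25 mmol/L trace has LBGI exactly 0 and HBGI
≈ 3·10⁻⁵, not exactly 0. ADRR averages daily (max low risk + max high
risk) and requires ≥ 1 full day. GMI = 3.31 + 0.02392·mean mg/dL. The
set is fixed but registered, so further kernels can be added without
touching the table builder. Every kernel is cross-checked in the tests
against an independent naive reimplementation to 10⁻⁹.

## 4. Models and evaluation

XGBoost regressors (`tree_method="hist"`, `max_bin=64` — the features
are smooth functionals of glucose and grams, and 64 histogram bins
reproduce 256-bin R to three decimals at ~2× speed; single thread for
determinism). Splits are participant-grouped (GroupShuffleSplit, test
size 0.2, 5 splits, seed 42). The hyperparameter grid spans
n_estimators 1000–4000, learning rate 0.001–0.01, depth 6–8, subsample
0.2–0.9, column subsample 0.3/0.6/0.9; selection is per split on an
inner grouped validation fold (20% of training groups), and analysis
drivers use a documented one-point grid (1000, 0.01, 6, 0.9, 0.9) for
tractability. The headline statistic is Pearson R over the pooled
out-of-sample predictions of all splits (pooled is statistically
stabler than averaging per-split Rs; both are reported). Rows must be
complete in every included feature group; a "no prior meal" sentinel
(NaN + indicator) keeps breakfasts in the data rather than letting a
non-null filter silently drop them. An optional median-imputation mode
fills missing side-table features with training-side medians (default
off). The carbohydrate-only model is the single `carbs_g` column.

Variance explanation fits plain linear models per feature group and
stratum and reports in-sample R²; rank-deficient designs drop collinear
columns via pivoted QR with a warning (temporal windows are nested, so
short-window sums are frequently collinear within a stratum).

Attribution uses exact TreeSHAP via xgboost's native `pred_contribs`
path enumeration; additivity (base value + Σ attributions = prediction)
is asserted, not assumed. The robustness surface retrains a
fixed-hyperparameter model per (participant count × train fraction)
cell with seeds derived per cell; hyperparameters are not re-tuned per
cell, which would confound the data-size effect with tuning noise. The
surface is parameterized by train fraction (the complementary test-size
phrasing maps as test = 1 − train fraction).

## 5. Determinism and numerics

One global seed fans out to per-stage seeds through counter-based
`SeedSequence` derivation, so stages are independently reproducible and
every derived seed stays below 2³¹. The generator is bit-reproducible
for a fixed config. Tolerances: iAUC agrees with a dense-grid oracle to
10⁻⁹ on gap-free piecewise-linear fixtures (same quadrature, different
route); generator-vs-pipeline agreement on noiseless isolated meals is
within 5%, the budget for 15-min sampling plus the ≤15-min grid offset
of the anchored window. Degenerate inputs: zero-carb meals get ratio 0;
empty windows yield missing features, not errors; meal exclusions are
data (flag + reason), not failures.

## 6. Known limitations

* **Measurement attenuation.** The minima-anchored 2-h window, under
  sensor noise and baseline wiggle, anchors slightly early on average
  and clips a truth-proportional share of the late excursion; together
  with trapezoid discretization this attenuates measured iAUC by ~5%
  relative to the generated truth (measured-on-true regression slope
  ≈ 0.93–0.95 at default noise). Consequently effect sizes estimated
  from the measured target — e.g. the macronutrient OLS slopes — are
  biased toward zero by a few percent, which exceeds 2 standard errors
  at n ≈ 5,000: a regression-dilution-type property of the measurement
  method itself, affecting real studies of this design equally. It is
  documented and tested rather than hidden by redefining the truth.
* The per-day sizes used in the shipped analyses (120–200 participants,
  14 days) are the package's chosen demonstration scale; all
  comparisons are within-cohort, so absolute R values scale with the
  generator's noise settings.
* Activity/sleep features are minimal (durations and recency); the
  generator couples them to nothing by default.
* MAGE deviates from smoothing-based implementations by design; see §3.
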