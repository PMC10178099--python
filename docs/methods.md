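# Methods

This note documents the models, the synthetic study conditions, the numerical
choices and the known limitations of `wheatrisk`.

## Problem setting

Weekly surveillance programs measure heavy-metal concentrations (Hg, Cd, As,
Pb, Cr) in wheat samples across provinces. The package turns such records
into three weekly province-level risk indicators, grades every
(province, week) point into data-driven risk levels, and predicts next-week
indicators — hence next-week risk levels — one step ahead, so inspection
resources can be targeted before an episode peaks.

## Risk indicators

For province *i*, week *t* and metal *j*, let C̄ᵢⱼ be the mean measured
concentration (mg/kg) over the week's samples, after every non-detect is
imputed at half its limit of detection (the WHO convention for low-level
contaminants when the non-detect share is moderate; here it is ~45%).

* **Single-factor index** Pᵢⱼ = C̄ᵢⱼ / Sⱼ, with Sⱼ the national limit for
  wheat (Hg 0.02, Cd 0.1, As 0.5, Pb 0.2, Cr 1.0 mg/kg).
* **NIPI** = √((P²ₘₐₓ + P̄²)/2), the Nemerow index, which overweights the
  worst metal while retaining the average.
* **THQ** (total target hazard quotient) = Σⱼ EF·ED·F₅₀·C̄ᵢⱼ / (RfDⱼ·W·AT),
  with intake frequency EF = 365 d/yr, exposure duration ED = 70 yr, body
  weight W = 60 kg, averaging time AT = 365·ED d, per-province mean wheat
  consumption F₅₀ (kg/d) and oral reference doses RfD of 0.0001, 0.001,
  0.0003, 0.0037 and 0.003 mg/(kg·d) for Hg, Cd, As, Pb, Cr. Because
  EF·ED/AT = 1, THQ reduces exactly to Σⱼ F₅₀·C̄ᵢⱼ/(RfDⱼ·W); the code keeps
  the full expression and the tests assert the identity.
* **TCR** (total carcinogenic risk) = Σⱼ EF·ED·CSFⱼ·EDIⱼ / ATC over the four
  carcinogenic metals (Cd, As, Pb, Cr — mercury has no oral slope factor),
  with EDIⱼ = F₅₀·C̄ᵢⱼ/W, slope factors 6.3, 1.5, 0.0085, 0.5 kg·d/mg and
  ATC = 365 × 70 d, so again the prefactor cancels.

Aggregation granularity is the (province, week) cell: substitution happens
per sample, averaging per cell, indicators per cell.

## Risk grading

Indicator triples are min-max normalized per dimension (extremes stored from
the fitting span; out-of-sample points are normalized with the same extremes
and deliberately not clipped). Clustering uses K-Means with
farthest-point seeding: the first center is a uniformly random point
(seeded), each further center the point with the largest distance to its
nearest chosen center; canonical D²-sampling initialization is available via
`d2_sampling=True`. Lloyd iterations run to an assignment fixpoint (cap
300); an empty cluster is re-seeded at the farthest point and logged. K is
chosen in 2..6 by the mean silhouette coefficient (ties to the smaller K).
Clusters are ordered into levels by the Euclidean distance of their centers
from the origin — for K = 3: Low, Medium, High (exact ties break on the
first coordinate, with a warning). New points take the label of the nearest
center; assignment ties go to the lower-risk label for determinism.

The pipeline fits normalization and clusters on the training span only
(weeks 1–138) so level definitions never see test data; standalone grading
(`wheatrisk grade`, `select_k`) fits on whatever span it is given, typically
the full dataset.

## Forecasting

One pyramid-attention model is fitted per (province, indicator) series
(60 models at defaults). The architecture:

1. **Embedding** — the standardized observation (linear 1→d), a learned
   embedding of the week-of-year covariate (fixed 52-week year; week 53
   wraps to 1), and a fixed sinusoidal positional encoding, summed.
   The covariate embedding is initialized at the same scale as the
   observation embedding so seasonal structure is salient from the start.
2. **Coarse-scale construction** — each coarser scale averages C consecutive
   finer nodes (the last node may own fewer when the count is not divisible
   by C) and applies a learned projection with ReLU. Defaults T = 24,
   C = 4, S = 3 give node counts (24, 6, 2).
3. **Pyramid attention** — one block of multi-head attention over the
   concatenated 32 nodes, masked so a query attends only to itself, its
   intra-scale neighbors within radius A = 1, its children and its parent;
   masked scores are set to −∞ before the softmax, so forbidden positions
   carry exactly zero weight (asserted bit-exactly in tests). Residual
   connections, layer norm and a position-wise feed-forward follow. The
   coarsest-scale nodes act as the global summary tokens.
4. **Head** — the final node of every scale is gathered, concatenated and
   mapped by an affine layer to the next standardized value, then
   de-standardized.

Training minimizes MSE with Adam (lr 10⁻³, batch 16, 200 epochs) over all
(24-week window → next value) pairs of the training span, seeded and fully
deterministic. Gaussian noise (sd 0.15 in standardized units) is added to
each training batch's observations; with only three years of data every
seasonal transition has at most two training examples, and without this
augmentation the network memorizes one year's exact history rather than
learning the week-of-year → level map, systematically under-predicting
episode onsets. Inference is teacher-forced one-step prediction: each test
week conditions on the actually observed preceding 24 weeks.

The attention stack is implemented on a small vectorized reverse-mode
autodiff engine written for this package (numpy arrays, ~15 primitives);
gradients are verified against central finite differences in the tests.

## Synthetic study conditions

Real provincial surveillance data are access-restricted, so the generator
emulates their structure: 20 provinces × 159 weeks (three years) × 5 metals
× 8 samples per cell (~127k records). Choices, fixed as the package's
default conditions:

* **Detection limits** (mg/kg): Hg 2·10⁻⁴, Cd 2·10⁻⁴, As 4·10⁻⁴, Pb 10⁻³,
  Cr 2·10⁻³ — instrument-level values typical of cold-vapor AAS, GF-AAS and
  ICP-MS assays. Baseline log-normal medians sit at the LODs, giving ~45%
  non-detects overall (consistent with a reported non-detectable share
  below 60%), all imputed at LOD/2. With these scales the quiet-week TCR is
  ~6·10⁻⁶ and episode weeks reach ~10⁻⁴, matching the magnitudes a
  three-level carcinogenic-risk grading spans.
* **Baseline noise**: per-sample log-sd 0.18 (Hg), 0.20 (Pb), 0.10
  (Cd/As/Cr). Averaging 8 samples per cell leaves weekly means tight; the
  half-censored mixture contributes most of the quiet-week variance.
* **Consumption**: one F₅₀ per province, uniform on [0.2, 0.4] kg/d. The
  interval keeps the between-province spread small enough that the three
  risk regimes remain essentially disjoint in indicator space, as the
  emulated study's per-cluster indicator ranges are.
* **Episode calendar** (week-of-year, recurring every year, all metals):
  national medium episodes at weeks 24–26 and 46–48 (mean ×3), a national
  high episode at weeks 40–41 (mean ×6), and an early-February (weeks 5–6)
  high episode in three provinces only, echoing the regional events
  surveillance reports describe. Episode severity carries a per
  (province, week) log-normal jitter (sd 0.08) shared across metals, so
  occurrences differ realistically between years and provinces. The
  resulting low/medium/high shares are roughly 84/12/4%, and both medium
  and high weeks fall in the train and test spans, which is what makes
  one-step level prediction learnable from the covariate.

Determinism: a single seed fans out through fixed `SeedSequence` spawn keys
(profiles, concentrations, grading, one per forecaster), so a configuration
plus seed reproduces the dataset byte for byte and the whole pipeline run
exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial correlation between neighboring provinces,
non-seasonal (unforecastable) contamination events, metal-specific episode
chemistry, laboratory batch effects and censoring that varies by lab, trends
across years, and realistic heavy-tailed concentration distributions
(real trace-contaminant GSDs are larger than the tight values used here;
tight values are needed for the weekly means of 8 samples to be as stable as
the emulated study's weekly series appear). Real consumption also varies far
more across China than the [0.2, 0.4] kg/d band.

## Evaluation

The split is train weeks 1–138, test weeks 139–159 (21 weeks × 20 provinces
= 420 test points). Indicator forecasts are scored per series with RMSE and
MAE; TCR residual metrics are multiplied by 10⁵ so all three indicators
share one order of magnitude. Level prediction is scored one-vs-rest per
level (precision/recall/F1 as percentages, two decimals) plus the full
confusion matrix; the true test-week level is the grading model's assignment
of the observed indicator triple, the predicted level its assignment of the
forecasted triple — the only self-consistent ground-truth construction when
levels are themselves model-defined. A persistence forecaster
(ŷ_{t+1} = y_t) is scored alongside as the sanity baseline.

## Numerical choices and degenerate inputs

* Constant series in `fit_forecaster` fall back to unit scale instead of
  dividing by zero.
* `minmax_fit` refuses constant dimensions; `silhouette_mean` refuses a
  single cluster; singleton clusters score zero silhouette.
* A non-detect without a positive LOD is a data error, never silently
  dropped.
* Censoring uses strict `value < LOD`; a value exactly at the LOD counts as
  detected.
* Lloyd's objective is non-increasing (property-tested); the empty-cluster
  re-seed is the only step that may break monotonicity and is logged.
* Seeds derived from the master seed are reduced mod 2³¹.

## Known limitations

* One model per series ignores cross-indicator and cross-province
  correlation; a multivariate or pooled model would share seasonal structure.
* The forecaster can only predict the conditional mean of an episode week;
  occurrence-level severity jitter is irreducible error, so level calls for
  points whose true severity lands near a cluster boundary remain uncertain.
* Silhouette-based K selection on a dominant-low-cluster geometry has small
  margins between K = 2, 3, 4; it is stable under the default conditions but
  not under arbitrarily rescaled episode calendars.
* Week-of-year uses a fixed 52-week year; calendar drift of real episodes
  (e.g., lunar-calendar holidays) would blur the covariate.
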